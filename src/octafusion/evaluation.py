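"""Cross-validated classification evaluation.

Six-fold (by default, stratified) cross-validation with accuracy,
sensitivity and specificity reported as fold means with Student-t 95%
confidence intervals, plus a pooled ROC curve and AUC over the
out-of-fold DR probabilities. The AUC is computed by trapezoidal
integration of the threshold-swept ROC and equals the Mann-Whitney
pair-counting statistic with ties credited 1/2.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold


# ---------------------------------------------------------------------------
# fold splitting
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # per-sample fold index in [0, k)
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def kfold_split(labels: Sequence[int], k: int = 6, seed: int = 0,
                stratified: bool = True) -> FoldSplit:
    """Deterministic (stratified) k-fold assignment of samples to folds."""
    labels = np.asarray([int(v) for v in labels])
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        counts = np.bincount(labels)
        if counts[counts > 0].min() < k:
            raise ValueError(
                f"minority class has {counts[counts > 0].min()} samples, "
                f"fewer than k={k}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if len(labels) < k:
            raise ValueError("fewer samples than folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldSplit(k=k, assignments=assignments, stratified=stratified)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ClsMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    ci_halfwidth: Optional[float] = None
    auc: Optional[float] = None


def confusion_metrics(pred_labels: Sequence[int], true_labels: Sequence[int],
                      positive_class: int = 1) -> ClsMetrics:
    pred = np.asarray([int(v) for v in pred_labels])
    true = np.asarray([int(v) for v in true_labels])
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    pp = pred == positive_class
    tp_ = true == positive_class
    tp = int((pp & tp_).sum())
    fp = int((pp & ~tp_).sum())
    fn = int((~pp & tp_).sum())
    tn = int((~pp & ~tp_).sum())
    if tp + fn == 0:
        warnings.warn("no positive samples: sensitivity is undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative samples: specificity is undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return ClsMetrics(accuracy=(tp + tn) / pred.size, sensitivity=sens,
                      specificity=spec, tp=tp, fp=fp, tn=tn, fn=fn)


def mean_ci(per_fold_values: Sequence[float], level: float = 0.95) -> Tuple[float, float]:
    """Fold mean with Student-t confidence half-width."""
    values = np.asarray(per_fold_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 fold values")
    k = values.size
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=k - 1)
    half = tcrit * values.std(ddof=1) / np.sqrt(k)
    return float(values.mean()), float(half)


def format_metric(mean: float, halfwidth: float, level: int = 95) -> str:
    """Render e.g. ``88.1% (95%CI ± 3.6%)``."""
    return f"{100 * mean:.1f}% ({level}%CI ± {100 * halfwidth:.1f}%)"


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> Tuple[np.ndarray, float]:
    """ROC points over all distinct score thresholds and the trapezoidal AUC.

    Returns (points, auc) where points is an (n, 2) array of (FPR, TPR)
    starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray([int(v) for v in truth])
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # cut only between distinct scores so ties move diagonally in one step
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(t == 1)[distinct]
    fps = np.cumsum(t == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_metrics: List[ClsMetrics]
    accuracy_mean: float
    accuracy_ci: float
    sensitivity_mean: float
    sensitivity_ci: float
    specificity_mean: float
    specificity_ci: float
    auc: float                       # pooled out-of-fold AUC
    fold_aucs: List[float]
    pooled: ClsMetrics               # metrics over all out-of-fold predictions
    pooled_scores: np.ndarray        # out-of-fold DR probability per sample
    pooled_roc: np.ndarray


def cross_validate(model_builder: Callable[[int], object], inputs: Sequence,
                   labels: Sequence[int], split: FoldSplit,
                   threshold: float = 0.5) -> CVResult:
    """Train a fresh model per fold and aggregate out-of-fold predictions.

    ``model_builder(fold_seed)`` must return an object with
    ``fit(X, y)`` and ``predict_proba(X) -> (n, 2)`` methods. Fold-level
    accuracy/sensitivity/specificity are aggregated as Student-t means; the
    out-of-fold DR probabilities are pooled into a single ROC/AUC.
    """
    labels = np.asarray([int(v) for v in labels])
    n = len(labels)
    pooled_scores = np.full(n, np.nan)
    pooled_pred = np.full(n, -1, dtype=np.int64)
    fold_metrics: List[ClsMetrics] = []
    fold_aucs: List[float] = []
    for fold in range(split.k):
        tr = split.train_indices(fold)
        te = split.test_indices(fold)
        model = model_builder(fold)
        model.fit([inputs[i] for i in tr], labels[tr])
        probs = np.asarray(model.predict_proba([inputs[i] for i in te]))
        scores = probs[:, 1]
        pred = (scores > threshold).astype(np.int64)
        pooled_scores[te] = scores
        pooled_pred[te] = pred
        fold_metrics.append(confusion_metrics(pred, labels[te]))
        if len(np.unique(labels[te])) == 2:
            fold_aucs.append(roc_auc(scores, labels[te])[1])
    acc_m, acc_h = mean_ci([m.accuracy for m in fold_metrics])
    sen_m, sen_h = mean_ci([m.sensitivity for m in fold_metrics])
    spe_m, spe_h = mean_ci([m.specificity for m in fold_metrics])
    roc_points, auc = roc_auc(pooled_scores, labels)
    pooled = confusion_metrics(pooled_pred, labels)
    pooled.auc = auc
    return CVResult(fold_metrics=fold_metrics,
                    accuracy_mean=acc_m, accuracy_ci=acc_h,
                    sensitivity_mean=sen_m, sensitivity_ci=sen_h,
                    specificity_mean=spe_m, specificity_ci=spe_h,
                    auc=auc, fold_aucs=fold_aucs, pooled=pooled,
                    pooled_scores=pooled_scores, pooled_roc=roc_points)


# ---------------------------------------------------------------------------
# harness baselines (also used as sanity oracles)
# ---------------------------------------------------------------------------

class MajorityClassifier:
    """Predicts the majority training class with certainty."""

    def fit(self, X, y):
        counts = np.bincount(np.asarray(y), minlength=2)
        self.majority = int(np.argmax(counts))
        return self

    def predict_proba(self, X):
        probs = np.zeros((len(X), 2))
        probs[:, self.majority] = 1.0
        return probs


class ScoreThresholdClassifier:
    """Scores each input by a scalar feature function (e.g. FAZ area)."""

    def __init__(self, feature: Callable[[object], float]):
        self.feature = feature

    def fit(self, X, y):
        f = np.asarray([self.feature(x) for x in X], dtype=np.float64)
        y = np.asarray(y)
        lo, hi = f.min(), max(f.max(), f.min() + 1e-9)
        self.lo, self.hi = lo, hi
        # orient and place the midpoint threshold by training accuracy
        best = (-1.0, 0.5, 1)
        for thr in np.unique(f):
            for sign in (1, -1):
                pred = ((sign * f) > (sign * thr)).astype(int)
                acc = (pred == y).mean()
                if acc > best[0]:
                    best = (acc, thr, sign)
        _, self.thr, self.sign = best
        return self

    def predict_proba(self, X):
        f = np.asarray([self.feature(x) for x in X], dtype=np.float64)
        z = (f - self.lo) / (self.hi - self.lo)
        p1 = np.clip(z if self.sign > 0 else 1.0 - z, 0.0, 1.0)
        # shift so the learned threshold sits at probability 0.5
        zt = (self.thr - self.lo) / (self.hi - self.lo)
        zt = zt if self.sign > 0 else 1.0 - zt
        p1 = np.clip(0.5 + (p1 - zt), 1e-6, 1 - 1e-6)
        return np.column_stack([1.0 - p1, p1])


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def results_to_csv(rows: Sequence[dict], path: str) -> None:
    """Ablation-style rows (input, model, metrics) to CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["input", "model", "accuracy", "ci", "sensitivity",
                         "specificity", "auc"])
        for r in rows:
            writer.writerow([
                r["input"], r["model"],
                f"{r['accuracy']:.4f}", f"{r['accuracy_ci']:.4f}",
                f"{r['sensitivity']:.4f}", f"{r['specificity']:.4f}",
                f"{r['auc']:.4f}",
            ])


def roc_to_csv(points: np.ndarray, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr"])
        for fpr, tpr in points:
            writer.writerow([f"{fpr:.6f}", f"{tpr:.6f}"])


def plot_roc(curves: dict, path: str) -> None:
    """``curves``: name -> (points, auc); writes a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (points, auc) in curves.items():
        ax.plot(points[:, 0], points[:, 1], label=f"{name} (AUC={auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
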