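"""Isolated-concatenated-block (ICB) residual classifier.

The network fuses two input-processing branches in front of a four-stage
residual backbone:

* the **isolated** process runs each input channel through its own
  (unshared) stem convolution, concatenates the per-channel feature maps,
  and integrates them with one further convolution + pooling;
* the **concatenated** process runs the full multi-channel input directly
  through a single stem convolution + pooling — with this branch alone the
  model is exactly the plain residual backbone (a ResNet50-style network).

Both branch outputs have the same spatial size and channel count and are
concatenated along channels when both branches are enabled. The backbone is
four stages of bottleneck residual blocks with stage counts (3, 4, 6, 3) —
each stage one projection-shortcut convolutional block followed by identity
blocks — ending in global average pooling and a softmax head over
{normal, DR}. ``width_multiplier`` scales every channel count so the
architecture can be exercised at desk scale.

The training loss is the categorical cross-entropy -sum_c t_c log f_c(x)
over the two diagnosis classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

EPS = 1e-7
STAGE_BLOCKS = (3, 4, 6, 3)
STAGE_WIDTHS = (64, 128, 256, 512)  # bottleneck (inner) widths at multiplier 1
STEM_WIDTH = 64


class BranchMode(str, Enum):
    ISOLATED_ONLY = "isolated_only"
    CONCATENATED_ONLY = "concatenated_only"
    BOTH = "both"


class InputMode(str, Enum):
    SEGMENTATION_ONLY = "segmentation_only"
    OCTA_ONLY = "octa_only"
    MERGED = "merged"


@dataclass(frozen=True)
class IcbVariant:
    branch_mode: BranchMode = BranchMode.BOTH
    input_mode: InputMode = InputMode.MERGED

    @property
    def in_channels(self) -> int:
        return 2 if self.input_mode == InputMode.MERGED else 1


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 bottleneck residual block.

    ``projection=True`` gives the convolutional block (shortcut through a
    strided 1x1 convolution); otherwise the identity block.
    """

    def __init__(self, in_ch: int, inner: int, out_ch: int, rng,
                 stride: int = 1, projection: bool = False):
        super().__init__()
        self.c1 = nn.ConvBnRelu(in_ch, inner, 1, rng, stride=stride, padding=0)
        self.c2 = nn.ConvBnRelu(inner, inner, 3, rng, padding=1)
        self.c3 = nn.Conv2d(inner, out_ch, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.projection = projection
        if projection:
            self.shortcut = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            self.bn_sc = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        h = self.bn3(self.c3(self.c2(self.c1(x))))
        sc = self.bn_sc(self.shortcut(x)) if self.projection else x
        return ag.relu(ag.add(h, sc))


class _ConcatenatedStem(nn.Module):
    """The whole input through one 7x7/2 convolution, then 3x3/2 max-pool."""

    def __init__(self, in_ch: int, width: int, rng):
        super().__init__()
        self.conv = nn.ConvBnRelu(in_ch, width, 7, rng, stride=2, padding=3)

    def forward(self, x):
        return ag.max_pool2d(self.conv(x), 3, 2, 1)


class _IsolatedStem(nn.Module):
    """Each channel through its own (unshared) 7x7/2 convolution at half
    width, concatenated, then one integrating 3x3 convolution + pooling so
    the output matches the concatenated stem's shape."""

    def __init__(self, in_ch: int, width: int, rng):
        super().__init__()
        sub = max(width // 2, 1)
        self.branches = [nn.ConvBnRelu(1, sub, 7, rng, stride=2, padding=3)
                         for _ in range(in_ch)]
        self.integrate = nn.ConvBnRelu(sub * in_ch, width, 3, rng, padding=1)

    def forward(self, x):
        C = x.shape[1]
        feats = [branch(_slice_channel(x, i)) for i, branch in enumerate(self.branches)]
        h = feats[0] if C == 1 else ag.concat(feats, axis=1)
        return ag.max_pool2d(self.integrate(h), 3, 2, 1)


def _slice_channel(x: Tensor, i: int) -> Tensor:
    data = x.data[:, i:i + 1]
    return ag._make(data, [(x, lambda g, i=i: _expand_channel(g, x.data.shape, i))])


def _expand_channel(g, shape, i):
    out = np.zeros(shape, dtype=g.dtype)
    out[:, i:i + 1] = g
    return out


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class ICBNet(nn.Module):
    def __init__(self, variant: IcbVariant, width_multiplier: float = 1.0,
                 n_classes: int = 2, seed: int = 0):
        super().__init__()
        self.variant = variant
        self.width_multiplier = width_multiplier
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1CB]))
        in_ch = variant.in_channels
        stem_w = max(int(round(STEM_WIDTH * width_multiplier)), 2)
        if variant.branch_mode in (BranchMode.ISOLATED_ONLY, BranchMode.BOTH):
            self.isolated = _IsolatedStem(in_ch, stem_w, rng)
        if variant.branch_mode in (BranchMode.CONCATENATED_ONLY, BranchMode.BOTH):
            self.concatenated = _ConcatenatedStem(in_ch, stem_w, rng)
        ch = stem_w * (2 if variant.branch_mode == BranchMode.BOTH else 1)
        self.stages: List[List[_Bottleneck]] = []
        for si, (n_blocks, w) in enumerate(zip(STAGE_BLOCKS, STAGE_WIDTHS)):
            inner = max(int(round(w * width_multiplier)), 2)
            out_ch = inner * 4
            stride = 1 if si == 0 else 2
            blocks = [_Bottleneck(ch, inner, out_ch, rng, stride=stride, projection=True)]
            blocks += [_Bottleneck(out_ch, inner, out_ch, rng) for _ in range(n_blocks - 1)]
            self.stages.append(blocks)
            ch = out_ch
        self.fc = nn.Linear(ch, n_classes, rng)
        # activations captured on every forward pass, for Grad-CAM
        self.features: Dict[str, Tensor] = {}

    @property
    def has_isolated_branch(self) -> bool:
        return hasattr(self, "isolated")

    @property
    def has_concatenated_branch(self) -> bool:
        return hasattr(self, "concatenated")

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.variant.in_channels:
            raise ValueError(
                f"{self.variant.input_mode.value} input requires "
                f"{self.variant.in_channels} channel(s), got {x.shape[1]}")
        self.features = {}
        outs = []
        if self.has_isolated_branch:
            outs.append(self.isolated(x))
        if self.has_concatenated_branch:
            outs.append(self.concatenated(x))
        h = outs[0] if len(outs) == 1 else ag.concat(outs, axis=1)
        self.features["stem"] = h
        for si, blocks in enumerate(self.stages, start=1):
            for b in blocks:
                h = b(h)
            self.features[f"stage{si}"] = h
        return self.fc(ag.mean_spatial(h))


def build_icb(variant: IcbVariant, width_multiplier: float = 1.0,
              seed: int = 0) -> ICBNet:
    return ICBNet(variant, width_multiplier=width_multiplier, seed=seed)


# ---------------------------------------------------------------------------
# loss and prediction
# ---------------------------------------------------------------------------

def cls_loss(prob: Sequence[float], truth: int, eps: float = EPS) -> float:
    """Categorical cross-entropy -sum_c t_c log f_c for one sample."""
    prob = np.asarray(prob, dtype=np.float64)
    if not np.isfinite(prob).all():
        raise ValueError("non-finite probabilities")
    onehot = np.eye(prob.shape[-1])[int(truth)]
    return float(-(onehot * np.log(np.clip(prob, eps, 1.0 - eps))).sum())


def predict_class(model: ICBNet, x: np.ndarray, tta: bool = False) -> np.ndarray:
    """Class probabilities for one (C, H, W) input or an (N, C, H, W) batch.

    With ``tta=True`` the probabilities are averaged over the four
    horizontal/vertical flip views, which stabilises borderline cases.
    """
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    views = [x]
    if tta:
        views += [x[:, :, ::-1], x[:, :, :, ::-1], x[:, :, ::-1, ::-1]]
    model.eval()
    acc = np.zeros((x.shape[0], 2))
    for v in views:
        with ag.no_grad():
            logits = model(Tensor(np.ascontiguousarray(v))).data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        acc += e / e.sum(axis=1, keepdims=True)
    probs = acc / len(views)
    return probs[0] if single else probs


def predict_label(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard label from the DR probability; ``threshold=0.5`` equals argmax."""
    return (np.asarray(probs)[..., 1] > threshold).astype(np.int64)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class ClsTrainConfig:
    epochs: int = 50
    batch_size: int = 8
    lr: float = 1e-4
    seed: int = 0
    augment: bool = False  # horizontal/vertical flips
    class_weights: Optional[Tuple[float, float]] = None


def train_classifier(model: ICBNet, samples: Sequence[Tuple[np.ndarray, int]],
                     config: ClsTrainConfig = ClsTrainConfig()) -> List[float]:
    """Mini-batch Adam on the cross-entropy; returns the per-epoch loss trace."""
    if len(samples) == 0:
        raise ValueError("empty training set")
    X = np.stack([np.asarray(x, dtype=np.float32) for x, _ in samples])
    if X.shape[1] != model.variant.in_channels:
        raise ValueError(
            f"training inputs have {X.shape[1]} channels but input_mode "
            f"{model.variant.input_mode.value} requires {model.variant.in_channels}")
    y = np.array([int(lab) for _, lab in samples])
    onehot = np.eye(2, dtype=np.float32)[y]
    if config.class_weights is not None:
        onehot = onehot * np.asarray(config.class_weights, dtype=np.float32)[y][:, None]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    model.train()
    trace: List[float] = []
    n = len(samples)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = X[idx]
            if config.augment:
                flips = rng.integers(0, 2, size=(len(idx), 2))
                xb = xb.copy()
                for i, (fh, fv) in enumerate(flips):
                    if fh:
                        xb[i] = xb[i, :, :, ::-1]
                    if fv:
                        xb[i] = xb[i, :, ::-1, :]
            loss = ag.cross_entropy_logits(model(Tensor(xb)), onehot[idx], EPS)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        trace.append(total / n)
    return trace


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_classifier(model: ICBNet, path: str) -> None:
    meta = json.dumps({"branch_mode": model.variant.branch_mode.value,
                       "input_mode": model.variant.input_mode.value,
                       "width_multiplier": model.width_multiplier})
    np.savez(path, __meta=np.array(meta), **model.state_arrays())


def load_classifier(path: str) -> ICBNet:
    data = np.load(path)
    meta = json.loads(str(data["__meta"]))
    variant = IcbVariant(BranchMode(meta["branch_mode"]), InputMode(meta["input_mode"]))
    model = ICBNet(variant, width_multiplier=meta["width_multiplier"])
    model.load_state_arrays({k: data[k] for k in data.files if k != "__meta"})
    return model


# ---------------------------------------------------------------------------
# ablation grid
# ---------------------------------------------------------------------------

def run_ablation_grid(images: Sequence[np.ndarray], masks: Sequence[np.ndarray],
                      labels: Sequence[int], width_multiplier: float = 1.0,
                      k: int = 6, train_config: Optional[ClsTrainConfig] = None,
                      seed: int = 0, threshold: float = 0.5) -> List[dict]:
    """Cross-validate every (branch_mode x input_mode) cell.

    Returns one row per cell with fold-mean accuracy and its 95% CI,
    sensitivity, specificity, and pooled AUC.
    """
    from . import evaluation, fusion

    if any(m is None for m in masks):
        raise ValueError("ablation grid requires a mask for every sample")
    train_config = train_config or ClsTrainConfig()
    labels = np.asarray([int(v) for v in labels])
    split = evaluation.kfold_split(labels, k=k, seed=seed, stratified=True)
    rows = []
    for input_mode in InputMode:
        X = [fusion.classifier_input(im, mk, input_mode.value)
             for im, mk in zip(images, masks)]
        for branch_mode in BranchMode:
            variant = IcbVariant(branch_mode, input_mode)

            def builder(fold_seed, variant=variant):
                return IcbClassifier(variant, width_multiplier=width_multiplier,
                                     train_config=train_config, seed=fold_seed)

            result = evaluation.cross_validate(builder, X, labels, split,
                                               threshold=threshold)
            rows.append({
                "input": input_mode.value,
                "model": branch_mode.value,
                "accuracy": result.accuracy_mean,
                "accuracy_ci": result.accuracy_ci,
                "sensitivity": result.sensitivity_mean,
                "specificity": result.specificity_mean,
                "auc": result.auc,
            })
    return rows


class IcbClassifier:
    """Adapter giving ICBNet the fit/predict contract of the evaluation
    harness (any classifier implementing it can be cross-validated)."""

    def __init__(self, variant: IcbVariant, width_multiplier: float = 1.0,
                 train_config: Optional[ClsTrainConfig] = None, seed: int = 0,
                 tta: bool = False):
        self.variant = variant
        self.width_multiplier = width_multiplier
        self.train_config = train_config or ClsTrainConfig()
        self.seed = seed
        self.tta = tta
        self.model: Optional[ICBNet] = None

    def fit(self, X: Sequence[np.ndarray], y: Sequence[int]) -> "IcbClassifier":
        self.model = build_icb(self.variant, self.width_multiplier, seed=self.seed)
        cfg = self.train_config
        cfg = ClsTrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
                             seed=self.seed, augment=cfg.augment,
                             class_weights=cfg.class_weights)
        train_classifier(self.model, list(zip(X, y)), cfg)
        return self

    def predict_proba(self, X: Sequence[np.ndarray]) -> np.ndarray:
        assert self.model is not None, "fit before predict"
        return predict_class(self.model, np.stack(X), tta=self.tta)
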