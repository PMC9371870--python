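"""Fold splitting, confusion metrics, CI aggregation, ROC/AUC, CV harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octafusion import evaluation as ev


class TestKFoldSplit:
    def test_partition_and_pigeonhole_on_default_cohort(self):
        labels = np.r_[np.zeros(244, int), np.ones(57, int)]
        split = ev.kfold_split(labels, k=6, seed=0)
        assert np.bincount(split.assignments).sum() == 301
        for fold in range(6):
            pos = labels[split.test_indices(fold)].sum()
            assert pos in (9, 10)

    def test_every_sample_in_exactly_one_fold(self):
        labels = np.random.default_rng(0).integers(0, 2, 40)
        split = ev.kfold_split(labels, k=4, seed=1)
        covered = np.concatenate([split.test_indices(f) for f in range(4)])
        assert sorted(covered) == list(range(40))

    def test_same_seed_reproduces_assignment(self):
        labels = np.random.default_rng(1).integers(0, 2, 30)
        a = ev.kfold_split(labels, k=3, seed=5)
        b = ev.kfold_split(labels, k=3, seed=5)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            ev.kfold_split([0, 1, 0, 1], k=1)
        with pytest.raises(ValueError):
            ev.kfold_split([0] * 10 + [1] * 2, k=3)  # minority too small

    def test_unstratified_mode(self):
        split = ev.kfold_split([0] * 10 + [1] * 2, k=3, stratified=False)
        assert np.bincount(split.assignments, minlength=3).sum() == 12


class TestConfusionMetrics:
    def test_hand_example(self):
        m = ev.confusion_metrics([1, 0, 0, 0], [1, 1, 0, 0])
        assert (m.tp, m.fn, m.tn, m.fp) == (1, 1, 2, 0)
        assert m.sensitivity == 0.5 and m.specificity == 1.0 and m.accuracy == 0.75

    def test_perfect_prediction(self):
        m = ev.confusion_metrics([0, 1, 1], [0, 1, 1])
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_positive_class_swap_exchanges_sens_and_spec(self):
        pred = [1, 0, 1, 0, 0]
        true = [1, 1, 0, 0, 0]
        a = ev.confusion_metrics(pred, true, positive_class=1)
        b = ev.confusion_metrics(pred, true, positive_class=0)
        assert a.sensitivity == b.specificity and a.specificity == b.sensitivity

    def test_undefined_sensitivity_warns_nan(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = ev.confusion_metrics([0, 1], [0, 0])
        assert np.isnan(m.sensitivity)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_metrics([0, 1], [0])


class TestMeanCI:
    def test_identical_values_zero_halfwidth(self):
        mean, half = ev.mean_ci([0.7, 0.7, 0.7])
        assert mean == pytest.approx(0.7) and half == pytest.approx(0.0)

    def test_two_fold_hand_value(self):
        mean, half = ev.mean_ci([0.8, 0.9])
        assert mean == pytest.approx(0.85)
        assert half == pytest.approx(12.7062 * np.std([0.8, 0.9], ddof=1) / np.sqrt(2),
                                     rel=1e-4)
        assert half == pytest.approx(0.635, abs=5e-4)

    def test_location_invariance(self):
        vals = [0.5, 0.6, 0.8]
        _, h1 = ev.mean_ci(vals)
        _, h2 = ev.mean_ci([v + 0.1 for v in vals])
        assert h1 == pytest.approx(h2)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ev.mean_ci([0.5])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = ev.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_complete_ties(self):
        _, auc = ev.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_four_sample_hand_value(self):
        _, auc = ev.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints(self):
        points, _ = ev.roc_auc([0.2, 0.6, 0.4], [0, 1, 1])
        np.testing.assert_array_equal(points[0], [0, 0])
        np.testing.assert_array_equal(points[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_sklearn_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
        truth = rng.integers(0, 2, n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        from sklearn.metrics import roc_auc_score
        _, auc = ev.roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)


class TestCrossValidate:
    def test_label_leaking_oracle_reaches_pooled_accuracy_one(self):
        labels = np.r_[np.zeros(24, int), np.ones(12, int)]
        rng = np.random.default_rng(0)
        rng.shuffle(labels)
        inputs = labels.astype(float)  # the input IS the label
        split = ev.kfold_split(labels, k=3, seed=0)
        result = ev.cross_validate(
            lambda seed: ev.ScoreThresholdClassifier(feature=float),
            inputs, labels, split)
        assert result.pooled.accuracy == 1.0
        assert result.auc == 1.0

    def test_out_of_fold_predictions_tile_dataset(self):
        labels = np.random.default_rng(3).integers(0, 2, 30)
        if labels.sum() < 3 or labels.sum() > 27:
            labels[:3] = [0, 1, 0]
        split = ev.kfold_split(labels, k=3, seed=2)
        result = ev.cross_validate(lambda seed: ev.MajorityClassifier(),
                                   labels.astype(float), labels, split)
        assert np.isfinite(result.pooled_scores).all()
        assert len(result.fold_metrics) == 3

    def test_fixed_seeds_reproduce_metrics(self):
        labels = np.r_[np.zeros(20, int), np.ones(10, int)]
        inputs = np.random.default_rng(4).random(30) + labels
        split = ev.kfold_split(labels, k=3, seed=9)

        def run():
            return ev.cross_validate(
                lambda seed: ev.ScoreThresholdClassifier(feature=float),
                inputs, labels, split)

        a, b = run(), run()
        assert a.accuracy_mean == b.accuracy_mean
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.pooled_scores, b.pooled_scores)


def test_format_metric_matches_reporting_style():
    assert ev.format_metric(0.881, 0.036) == "88.1% (95%CI ± 3.6%)"


def test_csv_and_plot_outputs(tmp_path):
    rows = [{"input": "merged", "model": "both", "accuracy": 0.9,
             "accuracy_ci": 0.02, "sensitivity": 0.8, "specificity": 0.95,
             "auc": 0.97}]
    csv_path = tmp_path / "rows.csv"
    ev.results_to_csv(rows, str(csv_path))
    assert "merged,both,0.9000" in csv_path.read_text()
    points, auc = ev.roc_auc([0.2, 0.8, 0.6], [0, 1, 1])
    roc_path = tmp_path / "roc.csv"
    ev.roc_to_csv(points, str(roc_path))
    assert roc_path.read_text().startswith("fpr,tpr")
    plot_path = tmp_path / "roc.png"
    ev.plot_roc({"model": (points, auc)}, str(plot_path))
    assert plot_path.exists()
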