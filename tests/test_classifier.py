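"""ICB architecture contracts, the classification loss, and training."""

import numpy as np
import pytest

from octafusion import classifier as cls
from octafusion import fusion, synth
from octafusion.classifier import BranchMode, IcbVariant, InputMode
from octafusion.nn.autograd import Tensor

WM = 0.125  # desk-scale width for architecture tests


def _random_input(channels, size=64, seed=0):
    return np.random.default_rng(seed).random((channels, size, size), dtype=np.float32)


class TestArchitecture:
    @pytest.mark.parametrize("branch_mode", list(BranchMode))
    @pytest.mark.parametrize("input_mode", list(InputMode))
    def test_all_variants_build_and_predict(self, branch_mode, input_mode):
        variant = IcbVariant(branch_mode, input_mode)
        model = cls.build_icb(variant, WM, seed=0)
        probs = cls.predict_class(model, _random_input(variant.in_channels))
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-5)
        assert (probs >= 0).all()

    def test_concatenated_only_is_plain_backbone(self):
        model = cls.build_icb(IcbVariant(BranchMode.CONCATENATED_ONLY, InputMode.MERGED), WM)
        assert not model.has_isolated_branch
        assert model.has_concatenated_branch

    def test_both_has_more_parameters_than_concatenated_only(self):
        both = cls.build_icb(IcbVariant(BranchMode.BOTH, InputMode.MERGED), WM)
        concat = cls.build_icb(IcbVariant(BranchMode.CONCATENATED_ONLY, InputMode.MERGED), WM)
        assert both.n_parameters() > concat.n_parameters()

    def test_isolated_branch_count_follows_channels(self):
        merged = cls.build_icb(IcbVariant(BranchMode.ISOLATED_ONLY, InputMode.MERGED), WM)
        octa = cls.build_icb(IcbVariant(BranchMode.ISOLATED_ONLY, InputMode.OCTA_ONLY), WM)
        assert len(merged.isolated.branches) == 2
        assert len(octa.isolated.branches) == 1

    def test_backbone_has_four_stages_with_resnet50_counts(self):
        model = cls.build_icb(IcbVariant(), WM)
        assert [len(stage) for stage in model.stages] == [3, 4, 6, 3]
        for stage in model.stages:
            assert stage[0].projection
            assert not any(b.projection for b in stage[1:])

    def test_channel_mismatch_rejected(self):
        model = cls.build_icb(IcbVariant(BranchMode.BOTH, InputMode.MERGED), WM)
        with pytest.raises(ValueError, match="channel"):
            model(Tensor(_random_input(1)[None]))


class TestClsLoss:
    def test_hand_values(self):
        assert cls.cls_loss((0.5, 0.5), 1) == pytest.approx(np.log(2), abs=1e-9)
        assert cls.cls_loss((0.0, 1.0), 1) == pytest.approx(0.0, abs=1e-6)
        assert cls.cls_loss((0.3, 0.7), 1) == pytest.approx(-np.log(0.7), abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cls.cls_loss((np.nan, 1.0), 0)


class TestPredictLabel:
    def test_zero_threshold_predicts_all_dr(self):
        probs = np.array([[0.99, 0.01], [0.4, 0.6]])
        np.testing.assert_array_equal(cls.predict_label(probs, threshold=0.0), [1, 1])

    def test_default_threshold_equals_argmax(self):
        probs = np.random.default_rng(0).dirichlet(np.ones(2), size=50)
        np.testing.assert_array_equal(cls.predict_label(probs, threshold=0.5),
                                      probs.argmax(axis=1))


class TestTraining:
    @pytest.fixture(scope="module")
    @staticmethod
    def quad():
        config = synth.SynthConfig(image_size=64, capillary_noise_sd=0.03, rng_seed=5)
        labels = [synth.Diagnosis.NORMAL] * 2 + [synth.Diagnosis.DR] * 2
        samples = [synth.generate_sample(config, lab, synth.sample_rng(config, i + 10))
                   for i, lab in enumerate(labels)]
        X = [fusion.classifier_input(s.image, s.mask, "merged") for s in samples]
        y = [int(s.label) for s in samples]
        return X, y

    def test_overfits_four_samples(self, quad):
        X, y = quad
        model = cls.build_icb(IcbVariant(), WM, seed=0)
        cls.train_classifier(model, list(zip(X, y)),
                             cls.ClsTrainConfig(epochs=80, batch_size=4, lr=1e-3, seed=0))
        pred = cls.predict_label(cls.predict_class(model, np.stack(X)))
        assert (pred == np.array(y)).all()

    def test_training_is_seed_deterministic(self, quad):
        X, y = quad

        def run():
            model = cls.build_icb(IcbVariant(), WM, seed=3)
            return cls.train_classifier(
                model, list(zip(X, y)),
                cls.ClsTrainConfig(epochs=3, batch_size=2, lr=1e-3, seed=11, augment=True))

        assert run() == run()

    def test_zero_learning_rate_freezes_weights_and_loss(self, quad):
        X, y = quad
        model = cls.build_icb(IcbVariant(), WM, seed=1)
        before = [p.data.copy() for p in model.parameters()]
        trace = cls.train_classifier(model, list(zip(X, y)),
                                     cls.ClsTrainConfig(epochs=3, batch_size=4, lr=0.0, seed=0))
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)
        # the loss is constant up to batch summation order (float32 noise)
        assert trace[0] == pytest.approx(trace[1], rel=1e-4)
        assert trace[1] == pytest.approx(trace[2], rel=1e-4)

    def test_input_mode_mismatch_rejected(self, quad):
        X, y = quad
        model = cls.build_icb(IcbVariant(BranchMode.BOTH, InputMode.OCTA_ONLY), WM)
        with pytest.raises(ValueError):
            cls.train_classifier(model, list(zip(X, y)))
        with pytest.raises(ValueError):
            cls.train_classifier(model, [])


def test_checkpoint_round_trip(tmp_path):
    model = cls.build_icb(IcbVariant(), WM, seed=4)
    x = _random_input(2)
    path = str(tmp_path / "icb.npz")
    cls.save_classifier(model, path)
    loaded = cls.load_classifier(path)
    assert loaded.variant == model.variant
    np.testing.assert_allclose(cls.predict_class(loaded, x),
                               cls.predict_class(model, x), atol=1e-6)


def test_ablation_grid_runs_all_nine_cells():
    config = synth.SynthConfig(image_size=64, capillary_noise_sd=0.03, rng_seed=8)
    samples = [synth.generate_sample(
        config, synth.Diagnosis.NORMAL if i % 2 == 0 else synth.Diagnosis.DR,
        synth.sample_rng(config, i)) for i in range(12)]
    rows = cls.run_ablation_grid(
        [s.image for s in samples], [s.mask for s in samples],
        [int(s.label) for s in samples],
        width_multiplier=0.0625, k=2,
        train_config=cls.ClsTrainConfig(epochs=1, batch_size=4, lr=1e-3, seed=0))
    assert len(rows) == 9
    assert {(r["input"], r["model"]) for r in rows} == {
        (i.value, b.value) for i in InputMode for b in BranchMode}
    for r in rows:
        assert 0.0 <= r["accuracy"] <= 1.0
        assert 0.0 <= r["auc"] <= 1.0
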