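"""Shared fixtures.

The expensive artifacts — the Monte-Carlo sample bank at generator defaults
and the two trained models — are session-scoped so that every test (and the
acceptance checks) reuses one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from octafusion import classifier, fusion, segmentation, synth
from octafusion.synth import Diagnosis


@pytest.fixture(scope="session")
def mc_bank():
    """200 samples per class at generator defaults (Monte-Carlo bank)."""
    config = synth.SynthConfig(rng_seed=0)
    samples = synth.generate_dataset(config, n_normal=200, n_dr=200)
    normal = [s for s in samples if s.label == Diagnosis.NORMAL]
    dr = [s for s in samples if s.label == Diagnosis.DR]
    return config, normal, dr


@pytest.fixture(scope="session")
def easy_bank():
    """180 low-noise samples, alternating classes, for end-to-end training."""
    config = synth.SynthConfig(capillary_noise_sd=0.03, rng_seed=11)
    samples = [synth.generate_sample(
        config, Diagnosis.NORMAL if i % 2 == 0 else Diagnosis.DR,
        synth.sample_rng(config, i)) for i in range(180)]
    return config, samples


@pytest.fixture(scope="session")
def trained_segmenter(easy_bank):
    """U-Net trained on 60 easy samples; held-out masks from 20 more."""
    _, samples = easy_bank
    train, test = samples[:60], samples[60:80]
    model = segmentation.build_unet(depth=4, base_filters=16, seed=0)
    trace = segmentation.train_segmenter(
        model, [(s.image, s.mask) for s in train],
        segmentation.SegTrainConfig(epochs=6, batch_size=4, lr=1e-3, seed=0))
    preds = np.stack([segmentation.predict_mask(model, s.image) for s in test])
    truths = np.stack([s.mask for s in test])
    metrics = segmentation.evaluate_segmentation(preds, truths)
    return {"model": model, "trace": trace, "test": test, "metrics": metrics}


@pytest.fixture(scope="session")
def trained_fusion_classifier(easy_bank):
    """(both, merged) ICB model trained on 120 easy samples with ground-truth
    label channels; flip-averaged probabilities on 60 held-out samples."""
    _, samples = easy_bank
    train, test = samples[:120], samples[120:]
    X_train = [fusion.classifier_input(s.image, s.mask, "merged") for s in train]
    y_train = [int(s.label) for s in train]
    model = classifier.build_icb(classifier.IcbVariant(), width_multiplier=0.25, seed=0)
    classifier.train_classifier(
        model, list(zip(X_train, y_train)),
        classifier.ClsTrainConfig(epochs=14, batch_size=16, lr=3e-4, seed=0, augment=True))
    classifier.train_classifier(
        model, list(zip(X_train, y_train)),
        classifier.ClsTrainConfig(epochs=6, batch_size=16, lr=8e-5, seed=100, augment=True))
    X_test = np.stack([fusion.classifier_input(s.image, s.mask, "merged") for s in test])
    y_test = np.array([int(s.label) for s in test])
    probs = classifier.predict_class(model, X_test, tta=True)
    return {"model": model, "test": test, "probs": probs, "y_test": y_test}
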