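"""U-Net segmentation of retinal vessels and the foveal avascular zone.

The segmenter maps a single-channel angiogram to a 3-class probability map
(background / vessel / FAZ). The contracting path halves the spatial size at
each level; the expansive path upsamples bilinearly and concatenates the
same-size contracting feature map through a skip connection; a final 1x1
convolution and per-pixel softmax produce the class probabilities, and the
predicted mask is the per-pixel argmax.

The training loss is per-pixel binary cross-entropy of each class channel
against the one-hot ground truth, summed over the three channels and
averaged over pixels, with probabilities clamped to [eps, 1-eps] before the
logarithm. With a softmax head this is the categorical cross-entropy plus
the (1 - y) log(1 - f) terms of the remaining channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

N_CLASSES = 3
EPS = 1e-7  # log clamp


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _DoubleConv(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.c1 = nn.ConvBnRelu(in_ch, out_ch, 3, rng)
        self.c2 = nn.ConvBnRelu(out_ch, out_ch, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x))


class _Up(nn.Module):
    """Bilinear x2 upsampling, 1x1 channel reduction, skip concat, conv."""

    def __init__(self, in_ch, skip_ch, out_ch, rng):
        super().__init__()
        self.reduce = nn.Conv2d(in_ch, skip_ch, 1, rng, bias=False)
        self.conv = _DoubleConv(2 * skip_ch, out_ch, rng)

    def forward(self, x, skip):
        h, w = skip.shape[2], skip.shape[3]
        x = ag.upsample_bilinear(x, h, w)
        x = self.reduce(x)
        return self.conv(ag.concat([skip, x], axis=1))


class UNet(nn.Module):
    def __init__(self, depth: int = 4, base_filters: int = 32,
                 n_classes: int = N_CLASSES, in_channels: int = 1, seed: int = 0):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        self.depth = depth
        widths = [base_filters * 2 ** i for i in range(depth + 1)]
        self.inc = _DoubleConv(in_channels, widths[0], rng)
        self.downs = [_DoubleConv(widths[i], widths[i + 1], rng) for i in range(depth)]
        self.ups = [_Up(widths[i + 1], widths[i], widths[i], rng)
                    for i in reversed(range(depth))]
        self.head = nn.Conv2d(widths[0], n_classes, 1, rng)
        self.bottleneck_shape: Tuple[int, int] | None = None

    def forward(self, x: Tensor) -> Tensor:
        side = x.shape[2]
        if side % (2 ** self.depth) != 0 or x.shape[3] % (2 ** self.depth) != 0:
            raise ValueError(
                f"input side {side} not divisible by 2^{self.depth}")
        skips = [self.inc(x)]
        h = skips[0]
        for down in self.downs:
            h = down(ag.max_pool2d(h, 2, 2))
            skips.append(h)
        self.bottleneck_shape = (h.shape[2], h.shape[3])
        for up, skip in zip(self.ups, skips[-2::-1]):
            h = up(h, skip)
        return self.head(h)


def build_unet(depth: int = 4, base_filters: int = 32,
               n_classes: int = N_CLASSES, seed: int = 0) -> UNet:
    return UNet(depth=depth, base_filters=base_filters, n_classes=n_classes, seed=seed)


# ---------------------------------------------------------------------------
# loss and inference
# ---------------------------------------------------------------------------

def _one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError("mask labels outside the class range")
    return np.eye(n_classes, dtype=np.float64)[mask]


def seg_loss(prob: np.ndarray, truth: np.ndarray, eps: float = EPS) -> float:
    """Per-pixel channelwise binary cross-entropy, averaged over pixels.

    ``prob``: (H, W, C) probability map; ``truth``: (H, W) integer mask.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim != 3:
        raise ValueError("prob must be (H, W, C)")
    if prob.shape[:2] != np.asarray(truth).shape:
        raise ValueError(f"shape mismatch: {prob.shape[:2]} vs {np.shape(truth)}")
    if not np.isfinite(prob).all():
        raise ValueError("non-finite probabilities")
    y = _one_hot(np.asarray(truth), prob.shape[2])
    f = np.clip(prob, eps, 1.0 - eps)
    h, w = prob.shape[:2]
    return float(-(y * np.log(f) + (1.0 - y) * np.log(1.0 - f)).sum() / (h * w))


def predict_prob(model: UNet, image: np.ndarray) -> np.ndarray:
    """Softmax probability map, (H, W, C)."""
    x = np.asarray(image, dtype=np.float32)[None, None]
    model.eval()
    with ag.no_grad():
        logits = model(Tensor(x))
    e = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    return probs[0].transpose(1, 2, 0)


def decode_prob(prob: np.ndarray) -> np.ndarray:
    """Per-pixel argmax of an (H, W, C) probability map.

    Ties resolve to the lowest class index.
    """
    return np.asarray(prob).argmax(axis=2).astype(np.uint8)


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Softmax + argmax decoding of the model output."""
    return decode_prob(predict_prob(model, image))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    epochs: int = 10
    batch_size: int = 4
    lr: float = 1e-3
    seed: int = 0


def train_segmenter(model: UNet, samples: Sequence[Tuple[np.ndarray, np.ndarray]],
                    config: SegTrainConfig = SegTrainConfig()) -> List[float]:
    """Mini-batch Adam on the channelwise BCE loss; returns per-epoch means."""
    if len(samples) == 0:
        raise ValueError("empty training set")
    shapes = {s[0].shape for s in samples}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent image shapes: {shapes}")
    X = np.stack([np.asarray(im, dtype=np.float32) for im, _ in samples])[:, None]
    Y = np.stack([_one_hot(np.asarray(m)) for _, m in samples]).transpose(0, 3, 1, 2)
    Y = Y.astype(np.float32)
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
            loss = ag.channel_bce_logits(model(Tensor(X[idx])), Y[idx], EPS)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        trace.append(total / n)
    return trace


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class SegMetrics:
    per_class_accuracy: np.ndarray   # one-vs-rest pixel accuracy per class
    per_class_iou: np.ndarray
    mean_accuracy: float
    miou: float


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray,
                          n_classes: int = N_CLASSES) -> SegMetrics:
    """Per-class one-vs-rest accuracy and IOU, plus their unweighted means.

    The IOU of a class absent from both prediction and truth is 1.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    n_pix = pred.size
    acc = np.empty(n_classes)
    iou = np.empty(n_classes)
    for c in range(n_classes):
        p = pred == c
        t = truth == c
        inter = int((p & t).sum())
        union = int((p | t).sum())
        iou[c] = inter / union if union else 1.0
        acc[c] = (n_pix - union + inter) / n_pix  # TP + TN over all pixels
    return SegMetrics(per_class_accuracy=acc, per_class_iou=iou,
                      mean_accuracy=float(acc.mean()), miou=float(iou.mean()))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_segmenter(model: UNet, path: str, depth: int | None = None,
                   base_filters: int | None = None) -> None:
    meta = {"depth": model.depth,
            "base_filters": model.inc.c1.conv.weight.shape[0]}
    np.savez(path, __meta_depth=meta["depth"], __meta_base=meta["base_filters"],
             **model.state_arrays())


def load_segmenter(path: str) -> UNet:
    data = np.load(path)
    model = build_unet(depth=int(data["__meta_depth"]),
                       base_filters=int(data["__meta_base"]))
    model.load_state_arrays({k: data[k] for k in data.files if not k.startswith("__meta")})
    return model
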