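"""Grad-CAM class-activation mapping for the classification models.

The channel weight of feature map ``M^l`` is the spatial average of the
gradient of the class score with respect to that channel,

    w_l = (1/N) * sum_ij  d f_C / d M^l_ij ,

and the activation map is ``ReLU(sum_l w_l M^l)``, bilinearly upsampled to
the input size. ``f_C`` is by default the pre-softmax logit of the class
(standard Grad-CAM practice, which avoids vanishing gradients when the
probability saturates); ``score_mode="sigmoid"`` routes the logit through a
sigmoid instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass
class CamHeatmap:
    values: np.ndarray            # (h, w) nonnegative, at feature-map resolution
    upsampled_values: np.ndarray  # (H, W) at input resolution
    weights: np.ndarray           # (L,) per-channel gradient weights


def grad_cam(model, x: np.ndarray, class_index: int, layer: str = "stage4",
             score_mode: str = "logit") -> CamHeatmap:
    """Heatmap of the spatial evidence for ``class_index`` at ``layer``.

    ``model`` must populate ``model.features`` (name -> activation Tensor)
    during its forward pass; the last residual stage is the default layer.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    if x.ndim == 3:
        x = x[None]
    model.eval()
    xt = Tensor(x, requires_grad=True)  # so even input-level layers get grads
    logits = model(xt)
    if not 0 <= class_index < logits.shape[1]:
        raise IndexError(f"class_index {class_index} out of range")
    if layer not in model.features:
        raise KeyError(f"layer {layer!r} not captured; available: "
                       f"{sorted(model.features)}")
    feature = model.features[layer]
    score = ag.select(logits, (0, class_index))
    if score_mode == "sigmoid":
        score = ag.sigmoid(score)
    elif score_mode != "logit":
        raise ValueError("score_mode must be 'logit' or 'sigmoid'")
    model.zero_grad()
    score.backward()
    if feature.grad is None:
        grads = np.zeros_like(feature.data)
    else:
        grads = feature.grad
    weights = grads[0].mean(axis=(1, 2))                     # (L,)
    raw = np.tensordot(weights, feature.data[0], axes=1)     # (h, w)
    values = np.maximum(raw, 0.0)
    upsampled = np.maximum(
        ag.upsample_bilinear_array(values, x.shape[2], x.shape[3]), 0.0)
    return CamHeatmap(values=values, upsampled_values=upsampled, weights=weights)


def overlay(image: np.ndarray, cam: CamHeatmap, alpha: float = 0.4) -> np.ndarray:
    """Blend the heatmap over the grayscale image as an RGB rendering.

    The heatmap is min-max normalised to [0, 1] (an all-zero map stays
    zero), mapped through the red-hot colormap, and blended in proportion
    to both ``alpha`` and the local heat, so unheated pixels keep their
    exact gray value. For merged 2-channel inputs, channel 0 (the raw
    angiogram) is the base image.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = image[0]
    heat = cam.upsampled_values
    if heat.shape != image.shape:
        raise ValueError(f"shape mismatch: {heat.shape} vs {image.shape}")
    span = heat.max() - heat.min()
    norm = (heat - heat.min()) / span if span > 0 else np.zeros_like(heat)
    cmap = matplotlib.colormaps["hot"]
    colored = cmap(norm)[..., :3]
    gray = np.repeat(np.clip(image, 0.0, 1.0)[..., None], 3, axis=2)
    w = (alpha * norm)[..., None]
    return (1.0 - w) * gray + w * colored
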