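"""Channel-level fusion of an angiogram with its segmentation.

The 3-class mask is encoded as a single grayscale label image using the
display convention black/gray/white: background -> 0.0, FAZ -> 0.5,
vessel -> 1.0. The label image is then stacked with the raw angiogram as
two independent channels — channel 0 is always the raw image, channel 1
the label image — with no rescaling, so both inputs are recoverable
bit-exactly from the merged image.

At classification time the label channel may come from ground-truth masks
or from a trained segmenter; deployment only has the latter.
"""

from __future__ import annotations

import csv
import os
from typing import List, Optional, Sequence

import numpy as np
import tifffile

from .synth import BACKGROUND, FAZ, VESSEL

# grayscale codes of the label image
LABEL_CODES = {BACKGROUND: 0.0, FAZ: 0.5, VESSEL: 1.0}


def encode_mask(mask: np.ndarray) -> np.ndarray:
    """Mask {0=background, 1=vessel, 2=FAZ} -> grayscale {0.0, 1.0, 0.5}."""
    mask = np.asarray(mask)
    if not np.isin(mask, list(LABEL_CODES)).all():
        raise ValueError("mask contains labels outside {0, 1, 2}")
    lut = np.array([LABEL_CODES[BACKGROUND], LABEL_CODES[VESSEL], LABEL_CODES[FAZ]],
                   dtype=np.float32)
    return lut[mask]


def decode_label(label_image: np.ndarray) -> np.ndarray:
    """Nearest-code decoding back to an integer mask (exact round trip)."""
    codes = np.array([LABEL_CODES[BACKGROUND], LABEL_CODES[VESSEL], LABEL_CODES[FAZ]])
    d = np.abs(np.asarray(label_image)[..., None] - codes)
    return d.argmin(axis=-1).astype(np.uint8)


def merge_channels(image: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Stack (angiogram, label image) along a new leading channel axis."""
    image = np.asarray(image)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {label.shape}")
    return np.stack([image, label.astype(image.dtype)], axis=0)


def classifier_input(image: np.ndarray, mask: Optional[np.ndarray],
                     input_mode: str) -> np.ndarray:
    """Build the (C, H, W) classifier input for a given input mode."""
    if input_mode == "octa_only":
        return np.asarray(image, dtype=np.float32)[None]
    if input_mode == "segmentation_only":
        if mask is None:
            raise ValueError("segmentation_only input requires a mask")
        return encode_mask(mask)[None]
    if input_mode == "merged":
        if mask is None:
            raise ValueError("merged input requires a mask")
        return merge_channels(np.asarray(image, dtype=np.float32), encode_mask(mask))
    raise ValueError(f"unknown input_mode {input_mode!r}")


# ---------------------------------------------------------------------------
# persistence: 2-page TIFF, or paired PNG-compatible arrays + manifest
# ---------------------------------------------------------------------------

def save_merged_tiff(merged: np.ndarray, path: str) -> None:
    tifffile.imwrite(path, np.asarray(merged, dtype=np.float32))


def load_merged_tiff(path: str) -> np.ndarray:
    return tifffile.imread(path)


def save_merged_pairs(merged_images: Sequence[np.ndarray], out_dir: str) -> str:
    """Paired float32 TIFF channels plus a CSV manifest; returns its path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "merged_manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["octa", "label"])
        for i, m in enumerate(merged_images):
            a, b = f"octa_{i:04d}.tiff", f"label_{i:04d}.tiff"
            tifffile.imwrite(os.path.join(out_dir, a), np.asarray(m[0], dtype=np.float32))
            tifffile.imwrite(os.path.join(out_dir, b), np.asarray(m[1], dtype=np.float32))
            writer.writerow([a, b])
    return manifest


def load_merged(path: str) -> List[np.ndarray]:
    """Load merged images from a 2-page TIFF file or a pairs manifest CSV."""
    if path.endswith(".csv"):
        out = []
        base = os.path.dirname(path)
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                a = tifffile.imread(os.path.join(base, row["octa"]))
                b = tifffile.imread(os.path.join(base, row["label"]))
                out.append(np.stack([a, b], axis=0))
        return out
    return [load_merged_tiff(path)]
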