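"""Synthetic OCTA angiogram generator.

Produces en-face angiogram-like images with the statistical structure the
rest of the pipeline assumes: bright branching vessel trees entering from
the image border, a mid-gray capillary speckle background, a dark central
foveal avascular zone (FAZ), plus per-pixel noise. Two diagnosis classes
are emulated: *normal*, and *DR* (diabetic-retinopathy-like) images that
have a larger FAZ and a lower perifoveal vessel density. The default class
imbalance mirrors a screening cohort of 244 normal / 57 DR eyes.

Everything is a pure function of ``SynthConfig.rng_seed``: one global seed
fans out to per-sample ``numpy.random.Generator`` streams keyed by the
sample counter, so any sample can be regenerated independently.

Pixel conventions: images are float32 in [0, 1]; masks are uint8 with
0 = background, 1 = vessel, 2 = FAZ.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from enum import IntEnum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

BACKGROUND, VESSEL, FAZ = 0, 1, 2


class Diagnosis(IntEnum):
    NORMAL = 0
    DR = 1


@dataclass(frozen=True)
class RadiusDist:
    """Gaussian radius distribution, in pixels."""
    mean: float
    sd: float


@dataclass(frozen=True)
class SynthConfig:
    image_size: int = 128
    faz_radius_normal: RadiusDist = field(default_factory=lambda: RadiusDist(12.0, 1.8))
    faz_radius_dr: RadiusDist = field(default_factory=lambda: RadiusDist(19.0, 2.8))
    n_seed_vessels: int = 12
    branch_prob: float = 0.08
    vessel_width_root: float = 2.6
    vessel_width_min: float = 1.0
    perifoveal_density_factor_dr: float = 0.55
    capillary_noise_sd: float = 0.05
    fov_scale: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_size < 64 or self.image_size % 16 != 0:
            raise ValueError("image_size must be >= 64 and divisible by 16")
        if not self.faz_radius_dr.mean > self.faz_radius_normal.mean:
            raise ValueError("DR mean FAZ radius must exceed the normal mean")
        if not 0.0 < self.perifoveal_density_factor_dr < 1.0:
            raise ValueError("perifoveal_density_factor_dr must lie in (0, 1)")
        if self.n_seed_vessels < 0:
            raise ValueError("n_seed_vessels must be nonnegative")


@dataclass
class SynthSample:
    image: np.ndarray          # (H, W) float32 in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1, 2}
    label: Diagnosis
    faz_radius: float = 0.0    # nominal (pre-deformation) radius in pixels


# ---------------------------------------------------------------------------
# FAZ geometry
# ---------------------------------------------------------------------------

def _draw_faz_radius(config: SynthConfig, label: Diagnosis, rng: np.random.Generator) -> float:
    dist = config.faz_radius_dr if label == Diagnosis.DR else config.faz_radius_normal
    r = rng.normal(dist.mean, dist.sd) * config.fov_scale
    return max(0.0, r)


def _faz_region(config: SynthConfig, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean FAZ region: a disc whose radius is modulated by low-order
    angular harmonics, so the boundary is lobed rather than circular."""
    size = config.image_size
    if radius < 1.0:
        # the 2..4-harmonic draws keep the rng stream aligned across branches
        rng.normal(size=3)
        rng.uniform(size=3)
        return np.zeros((size, size), dtype=bool)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - c, xx - c
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    amp = rng.normal(0.0, 0.06, size=3)
    phase = rng.uniform(0.0, 2 * np.pi, size=3)
    mod = np.ones_like(theta)
    for k, (a, p) in enumerate(zip(amp, phase), start=2):
        mod += a * np.cos(k * theta + p)
    mod = np.clip(mod, 0.6, 1.4)  # keeps the region star-shaped about the centre
    return dist <= radius * mod


# ---------------------------------------------------------------------------
# vessel growth
# ---------------------------------------------------------------------------

def _stamp_disc(canvas: np.ndarray, y: float, x: float, radius: float) -> None:
    size = canvas.shape[0]
    r = max(radius, 0.8)  # keeps consecutive stamps of a path 8-connected
    y0, y1 = int(max(0, np.floor(y - r))), int(min(size - 1, np.ceil(y + r)))
    x0, x1 = int(max(0, np.floor(x - r))), int(min(size - 1, np.ceil(x + r)))
    if y1 < y0 or x1 < x0:
        return
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    canvas[y0:y1 + 1, x0:x1 + 1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r * r


def grow_vessel_tree(config: SynthConfig, label: Diagnosis, rng: np.random.Generator,
                     faz_region: Optional[np.ndarray] = None,
                     faz_radius: Optional[float] = None) -> np.ndarray:
    """Grow a binary vessel map by a biased random walk with bifurcation.

    Root vessels enter from the image border heading inward, meander with
    directional persistence, taper in width, and bifurcate with probability
    ``branch_prob`` per growth step. Vessels steer around — and are never
    drawn inside — the FAZ region. For DR samples, growth steps that fall in
    the perifoveal annulus [r, 2r] are drawn only with probability
    ``perifoveal_density_factor_dr``, thinning the perifoveal plexus.
    """
    config.validate()
    size = config.image_size
    if faz_radius is None:
        faz_radius = _draw_faz_radius(config, label, rng)
    if faz_region is None:
        faz_region = _faz_region(config, faz_radius, rng)
    canvas = np.zeros((size, size), dtype=bool)
    if config.n_seed_vessels == 0:
        return canvas
    c = (size - 1) / 2.0
    step_len = 0.9
    max_steps = int(1.1 * size)
    thin = config.perifoveal_density_factor_dr if label == Diagnosis.DR else 1.0

    # evenly spaced entry angles with jitter; roots start just outside the frame
    base = rng.uniform(0.0, 2 * np.pi)
    angles = base + np.arange(config.n_seed_vessels) * (2 * np.pi / config.n_seed_vessels)
    angles = angles + rng.normal(0.0, 0.12, size=config.n_seed_vessels)

    stack: List[Tuple[float, float, float, float, int]] = []  # y, x, heading, width, steps_left
    for a in angles:
        # place the root on the square border along the ray at angle a
        t = (size / 2.0 - 1.0) / max(abs(np.sin(a)), abs(np.cos(a)))
        y = c + t * np.sin(a)
        x = c + t * np.cos(a)
        heading = a + np.pi + rng.normal(0.0, 0.25)  # point inward
        stack.append((y, x, heading, config.vessel_width_root, max_steps))

    gap_len = 4  # steps per dropout gap; long enough to break stamp overlap
    while stack:
        y, x, heading, width, steps = stack.pop()
        entered = False
        gap = 0
        for _ in range(steps):
            heading += rng.normal(0.0, 0.16)
            y += step_len * np.sin(heading)
            x += step_len * np.cos(heading)
            inside = 0 <= y < size and 0 <= x < size
            if inside:
                entered = True
            elif entered:  # a path that leaves the frame terminates there
                break
            d = np.hypot(y - c, x - c)
            if d > size:
                break
            # steer around the FAZ: once close, rotate the heading tangentially
            if faz_radius > 0 and d < 1.25 * faz_radius + width:
                away = np.arctan2(y - c, x - c)
                heading += 0.5 * np.sign(np.sin(heading - away) + 1e-9)
            width = max(config.vessel_width_min, width - 0.012 * config.vessel_width_root)
            in_annulus = faz_radius > 0 and faz_radius <= d <= 2.0 * faz_radius
            if gap > 0:
                gap -= 1
                continue
            if in_annulus and thin < 1.0 and rng.random() > thin:
                gap = gap_len  # perifoveal dropout: suppress a whole segment
                continue
            _stamp_disc(canvas, y, x, width / 2.0)
            if rng.random() < config.branch_prob and width > config.vessel_width_min:
                child_heading = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.35, 0.8)
                stack.append((y, x, child_heading, width * 0.75, steps // 2))
    canvas &= ~faz_region
    return canvas


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BACKGROUND_LEVEL = 0.35
_FAZ_LEVEL = 0.08
_VESSEL_LEVEL = 0.92


def generate_sample(config: SynthConfig, label: Diagnosis,
                    rng: np.random.Generator) -> SynthSample:
    """Render one angiogram + mask + diagnosis label.

    The image is composed of a capillary-texture background (mid-gray
    speckle whose amplitude scales with ``capillary_noise_sd``), bright
    vessels, a dark FAZ disc, and additive Gaussian noise, clipped to [0, 1].
    """
    config.validate()
    size = config.image_size
    faz_radius = _draw_faz_radius(config, label, rng)
    faz_region = _faz_region(config, faz_radius, rng)
    vessels = grow_vessel_tree(config, label, rng, faz_region=faz_region,
                               faz_radius=faz_radius)

    noise_sd = config.capillary_noise_sd
    image = np.full((size, size), _BACKGROUND_LEVEL, dtype=np.float64)
    # capillary plexus: band-passed speckle, amplitude tied to the noise knob
    speckle = rng.normal(0.0, 1.0, (size, size))
    image += 2.5 * noise_sd * gaussian_filter(speckle, sigma=1.0)
    image[faz_region] = _FAZ_LEVEL + 0.3 * (image[faz_region] - _BACKGROUND_LEVEL)
    image[vessels] = _VESSEL_LEVEL
    image = gaussian_filter(image, sigma=0.5)
    image += rng.normal(0.0, noise_sd, (size, size)) if noise_sd > 0 else 0.0
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[vessels] = VESSEL
    mask[faz_region] = FAZ
    return SynthSample(image=image, mask=mask, label=label, faz_radius=faz_radius)


def sample_rng(config: SynthConfig, index: int) -> np.random.Generator:
    """Per-sample stream: the global seed fanned out by the sample counter."""
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed, index]))


def generate_dataset(config: SynthConfig, n_normal: int = 244,
                     n_dr: int = 57) -> List[SynthSample]:
    """Generate ``n_normal + n_dr`` samples in a deterministic shuffled order."""
    config.validate()
    if n_normal < 0 or n_dr < 0:
        raise ValueError("sample counts must be nonnegative")
    labels = np.array([Diagnosis.NORMAL] * n_normal + [Diagnosis.DR] * n_dr)
    order_rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1 << 20]))
    order_rng.shuffle(labels)
    return [generate_sample(config, Diagnosis(int(lab)), sample_rng(config, i))
            for i, lab in enumerate(labels)]


# ---------------------------------------------------------------------------
# measurements used by tests and the evaluation harness
# ---------------------------------------------------------------------------

def faz_area(mask: np.ndarray) -> int:
    """FAZ pixel count — the simple biomarker that separates the classes."""
    return int((mask == FAZ).sum())


def annulus_vessel_density(vessel_map: np.ndarray, radius: float,
                           outer_factor: float = 2.0) -> float:
    """Vessel-pixel fraction in the perifoveal annulus [radius, outer*radius]."""
    size = vessel_map.shape[0]
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(yy - c, xx - c)
    ring = (d >= radius) & (d <= outer_factor * radius)
    if not ring.any():
        return 0.0
    return float((vessel_map > 0)[ring].mean())


# ---------------------------------------------------------------------------
# on-disk format: 8-bit PNGs plus a CSV manifest
# ---------------------------------------------------------------------------

_MASK_PALETTE = {BACKGROUND: 0, FAZ: 128, VESSEL: 255}
_PALETTE_MASK = {0: BACKGROUND, 128: FAZ, 255: VESSEL}


def save_dataset(samples: Sequence[SynthSample], out_dir: str,
                 folds: Optional[Sequence[int]] = None) -> str:
    """Write images/masks as 8-bit PNG and a manifest CSV; returns its path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "mask_filename", "label", "fold"])
        for i, s in enumerate(samples):
            img_name, mask_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8), mode="L").save(
                os.path.join(out_dir, img_name))
            enc = np.zeros_like(s.mask)
            for k, v in _MASK_PALETTE.items():
                enc[s.mask == k] = v
            Image.fromarray(enc, mode="L").save(os.path.join(out_dir, mask_name))
            fold = folds[i] if folds is not None else -1
            writer.writerow([img_name, mask_name, int(s.label), fold])
    return manifest


def load_dataset(out_dir: str) -> List[SynthSample]:
    samples = []
    with open(os.path.join(out_dir, "manifest.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(os.path.join(out_dir, row["filename"])),
                               dtype=np.float32) / 255.0
            enc = np.asarray(Image.open(os.path.join(out_dir, row["mask_filename"])))
            mask = np.zeros_like(enc, dtype=np.uint8)
            for v, k in _PALETTE_MASK.items():
                mask[enc == v] = k
            samples.append(SynthSample(image=image, mask=mask,
                                       label=Diagnosis(int(row["label"]))))
    return samples
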