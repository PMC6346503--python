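"""Synthetic speckle phantoms with one grade-linked lesion per image.

The generator emulates the properties of B-mode breast ultrasound that
drive the pipeline's design without simulating acoustics: a Rayleigh
speckle background (the standard envelope model for fully developed
speckle) blurred by a small Gaussian point-spread stand-in, and a single
hypoechoic lesion whose boundary morphology encodes the BI-RADS-style
grade.  Grade "3" lesions are smooth ovals; higher grades add
progressively stronger low-frequency boundary roughness and discrete
spicule-like spikes, so that a boundary-irregularity statistic increases
monotonically in expectation from grade "3" to grade "5".

All randomness flows from a single seed; rendering a spec twice yields
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label
from skimage.measure import perimeter as mask_perimeter

from . import io as egio
from .metrics import GRADE_INDEX, GRADE_VALUES

DEFAULT_SIZE = 288
FRAME_MARGIN = 8  # minimum px between lesion and frame edge

# Per-grade morphology ranges (low, high); monotone in the grade index.
_IRREGULARITY_RANGES = ((0.00, 0.05), (0.08, 0.15), (0.15, 0.25), (0.25, 0.35), (0.35, 0.50))
_SPICULE_RANGES = ((0, 0), (1, 2), (2, 4), (4, 6), (6, 10))
_SPIKE_AMP_RANGE = (0.15, 0.30)
_SPIKE_WIDTH_RANGE = (0.06, 0.12)  # radians
_RADIUS_FRAC_RANGE = (0.09, 0.16)  # semi-axis as a fraction of frame size
_CONTRAST_RANGE = (0.15, 0.35)
_SPECKLE_SCALE = 0.25
# Radial factor is clipped to this band, bounding the lesion extent.
_FACTOR_CLIP = (0.25, 1.75)

# Clinical case-count proportions used by the ratio preset.
CLINICAL_PROPORTIONS = {"3": 531, "4A": 443, "4B": 376, "4C": 565, "5": 323}

__all__ = [
    "PhantomSpec",
    "sample_phantom_spec",
    "render_phantom",
    "generate_dataset",
    "shape_compactness",
    "DEFAULT_SIZE",
    "CLINICAL_PROPORTIONS",
]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic lesion image."""

    grade: str
    center: tuple[float, float]  # (row, col), px
    base_radii: tuple[float, float]  # ellipse semi-axes (a=row, b=col), px
    irregularity_amp: float  # dimensionless, [0, 0.6]
    spicule_count: int
    lesion_contrast: float  # intensity offset, [0.1, 0.5]
    speckle_scale: float  # Rayleigh sigma
    seed: int
    size: int = DEFAULT_SIZE
    n_distractors: int = 0  # bright ligament-like streaks outside the lesion

    def __post_init__(self):
        if self.grade not in GRADE_INDEX:
            raise ValueError(f"unknown grade {self.grade!r}")
        if not 0.0 <= self.irregularity_amp <= 0.6:
            raise ValueError("irregularity_amp outside [0, 0.6]")
        if self.spicule_count < 0:
            raise ValueError("spicule_count must be >= 0")
        if not 0.1 <= self.lesion_contrast <= 0.5:
            raise ValueError("lesion_contrast outside [0.1, 0.5]")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        reach = max(self.base_radii) * _FACTOR_CLIP[1]
        for c in self.center:
            if c - reach < FRAME_MARGIN or c + reach > self.size - FRAME_MARGIN:
                raise ValueError("lesion may escape the frame margin")


def sample_phantom_spec(grade: str, rng: np.random.Generator,
                        size: int = DEFAULT_SIZE) -> PhantomSpec:
    """Draw morphology parameters from the grade-specific ranges."""
    if grade not in GRADE_INDEX:
        raise ValueError(f"unknown grade {grade!r}")
    gi = GRADE_INDEX[grade]
    irr = float(rng.uniform(*_IRREGULARITY_RANGES[gi]))
    sp_lo, sp_hi = _SPICULE_RANGES[gi]
    spicules = int(rng.integers(sp_lo, sp_hi + 1))
    a = float(rng.uniform(*_RADIUS_FRAC_RANGE) * size)
    b = float(rng.uniform(*_RADIUS_FRAC_RANGE) * size)
    reach = max(a, b) * _FACTOR_CLIP[1]
    lo = FRAME_MARGIN + reach
    hi = size - FRAME_MARGIN - reach
    if hi <= lo:
        raise ValueError(f"frame size {size} too small for sampled lesion radii")
    center = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
    contrast = float(rng.uniform(*_CONTRAST_RANGE))
    seed = int(rng.integers(0, 2**31 - 1))
    return PhantomSpec(grade=grade, center=center, base_radii=(a, b),
                       irregularity_amp=irr, spicule_count=spicules,
                       lesion_contrast=contrast, speckle_scale=_SPECKLE_SCALE,
                       seed=seed, size=size)


def _lesion_radius(spec: PhantomSpec, rng: np.random.Generator,
                   theta: np.ndarray) -> np.ndarray:
    a, b = spec.base_radii
    # r(0) = b along columns, r(pi/2) = a along rows
    ellipse = a * b / np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    rough = np.zeros_like(theta)
    for k in range(2, 6):
        rough += rng.uniform(-1.0, 1.0) / k * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    peak = np.abs(rough).max()
    if peak > 0:
        rough *= spec.irregularity_amp / peak
    spikes = np.zeros_like(theta)
    for _ in range(spec.spicule_count):
        loc = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(*_SPIKE_AMP_RANGE)
        width = rng.uniform(*_SPIKE_WIDTH_RANGE)
        delta = np.angle(np.exp(1j * (theta - loc)))  # wrapped difference
        spikes += amp * np.exp(-0.5 * (delta / width) ** 2)
    factor = np.clip(1.0 + rough + spikes, *_FACTOR_CLIP)
    return ellipse * factor


def render_phantom(spec: PhantomSpec, smooth_sigma: float = 0.8,
                   n_theta: int = 720):
    """Render one phantom.

    Returns ``(image, mask, grade)``: a float image in [0, 1] of shape
    (size, size), a boolean lesion mask, and the grade string.  The
    image is the Gaussian-smoothed Rayleigh speckle field minus
    ``lesion_contrast`` inside the mask (hypoechoic lesion), clipped to
    [0, 1].  ``smooth_sigma = 0`` skips the PSF blur.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = _lesion_radius(spec, rng, theta)
    rows = spec.center[0] + r * np.sin(theta)
    cols = spec.center[1] + r * np.cos(theta)
    if (rows.min() < FRAME_MARGIN or cols.min() < FRAME_MARGIN
            or rows.max() > spec.size - FRAME_MARGIN
            or cols.max() > spec.size - FRAME_MARGIN):
        raise ValueError("rendered lesion escapes the frame margin")
    mask = np.zeros((spec.size, spec.size), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    speckle = rng.rayleigh(scale=spec.speckle_scale, size=(spec.size, spec.size))
    if smooth_sigma > 0:
        speckle = ndimage.gaussian_filter(speckle, smooth_sigma)
    if spec.n_distractors:
        speckle = speckle + _distractor_field(spec, rng) * ~mask
    img = np.clip(speckle - spec.lesion_contrast * mask, 0.0, 1.0)
    return img, mask, spec.grade


def _distractor_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Bright streaks mimicking ligament-like structures (outside the lesion)."""
    yy, xx = np.mgrid[0:spec.size, 0:spec.size].astype(float)
    field = np.zeros((spec.size, spec.size))
    for _ in range(spec.n_distractors):
        angle = rng.uniform(0, np.pi)
        offset = rng.uniform(0.2, 0.8) * spec.size
        width = rng.uniform(1.5, 3.5)
        amp = rng.uniform(0.2, 0.4)
        # signed distance to the line x sin(a) - y cos(a) = offset - size/2
        d = xx * np.sin(angle) - yy * np.cos(angle) - (offset - spec.size / 2.0)
        field += amp * np.exp(-0.5 * (d / width) ** 2)
    return field


def shape_compactness(mask: np.ndarray) -> float:
    """Boundary irregularity statistic perimeter^2 / (4 pi area); 1 for a disk."""
    mask = np.asarray(mask, dtype=bool)
    area = mask.sum()
    if area == 0:
        raise ValueError("empty mask")
    p = mask_perimeter(mask)
    return float(p * p / (4.0 * np.pi * area))


def _grade_counts(n_per_grade: int, ratios) -> dict[str, int]:
    if ratios is None:
        return {g: n_per_grade for g in GRADE_VALUES}
    if ratios == "clinical":
        props = CLINICAL_PROPORTIONS
    else:
        props = {g: float(ratios[g]) for g in GRADE_VALUES}
    total = 5 * n_per_grade
    weight = sum(props.values())
    counts = {g: max(1, round(total * props[g] / weight)) for g in GRADE_VALUES}
    return counts


def generate_dataset(n_per_grade: int, out_dir, seed: int,
                     size: int = DEFAULT_SIZE, ratios=None,
                     smooth_sigma: float = 0.8) -> pd.DataFrame:
    """Write a phantom dataset (images/, masks/, manifest.csv) to disk.

    Balanced by default (``n_per_grade`` per grade); ``ratios="clinical"``
    keeps the same total but splits it according to the clinical
    case-count proportions.  Regeneration with the same seed is
    byte-identical.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = _grade_counts(n_per_grade, ratios)
    rows = []
    idx = 0
    for grade in GRADE_VALUES:
        for _ in range(counts[grade]):
            spec = sample_phantom_spec(grade, rng, size=size)
            img, mask, _ = render_phantom(spec, smooth_sigma=smooth_sigma)
            stem = f"phantom_{idx:05d}"
            egio.write_image(out_dir / "images" / f"{stem}.png", img)
            egio.write_mask(out_dir / "masks" / f"{stem}.png", mask)
            rows.append({"image": f"images/{stem}.png",
                         "mask": f"masks/{stem}.png",
                         "label": grade})
            idx += 1
    frame = pd.DataFrame(rows, columns=list(egio.MANIFEST_COLUMNS))
    frame.to_csv(out_dir / "manifest.csv", index=False)
    return frame


def render_batch(grades, seed: int, size: int = DEFAULT_SIZE,
                 smooth_sigma: float = 0.8):
    """Render a list of phantoms in memory; returns (images, masks, labels)."""
    rng = np.random.default_rng(seed)
    imgs, masks, labels = [], [], []
    for g in grades:
        spec = sample_phantom_spec(g, rng, size=size)
        img, mask, _ = render_phantom(spec, smooth_sigma=smooth_sigma)
        imgs.append(img)
        masks.append(mask)
        labels.append(g)
    return np.stack(imgs), np.stack(masks), labels


def is_single_component(mask: np.ndarray) -> bool:
    lab, n = cc_label(np.asarray(mask, bool), connectivity=2, return_num=True)
    return n == 1
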