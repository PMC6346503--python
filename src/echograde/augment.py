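"""The two augmentation policies of the training recipes.

The identification (ROI) policy applies random brightness, contrast,
translation and horizontal flip followed by standardization, drawn
fresh every epoch so that N epochs see N augmented variants of each
image; translations are clamped so the full lesion mask always stays in
frame.  The grading policy expands each sample exactly four times
offline with translation only, the last two copies additionally
flipped, leaving pixel statistics otherwise untouched.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["AugPolicy", "augment_roi_sample", "augment_grade_sample",
           "standardize", "translate", "expand_grade_dataset"]


@dataclasses.dataclass(frozen=True)
class AugPolicy:
    """Transform ranges; photometric ranges apply to the ROI policy only."""

    kind: str = "roi"  # "roi" | "grade"
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    max_shift: int = 20
    flip_prob: float = 0.5

    def __post_init__(self):
        if self.kind not in ("roi", "grade"):
            raise ValueError(f"unknown policy kind {self.kind!r}")


def translate(img: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer translation with edge replication."""
    dr, dc = int(shift[0]), int(shift[1])
    h, w = img.shape
    out = np.pad(img, ((abs(dr),) * 2, (abs(dc),) * 2), mode="edge")
    r0 = abs(dr) - dr
    c0 = abs(dc) - dc
    return out[r0:r0 + h, c0:c0 + w]


def standardize(img: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance normalization of one image."""
    img = np.asarray(img, dtype=np.float64)
    sd = img.std()
    if sd == 0:
        warnings.warn("constant image: standardization returns zeros")
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def _feasible_shift(mask: np.ndarray, max_shift: int,
                    rng: np.random.Generator) -> tuple[int, int]:
    """Draw a translation that keeps every mask pixel inside the frame."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h, w = mask.shape
    lo_r = -min(max_shift, rows[0])
    hi_r = min(max_shift, h - 1 - rows[-1])
    lo_c = -min(max_shift, cols[0])
    hi_c = min(max_shift, w - 1 - cols[-1])
    return (int(rng.integers(lo_r, hi_r + 1)), int(rng.integers(lo_c, hi_c + 1)))


def augment_roi_sample(img: np.ndarray, mask: np.ndarray,
                       rng: np.random.Generator,
                       policy: AugPolicy | None = None):
    """One draw of the identification-policy transform chain.

    Returns ``(image, mask)``: the same geometric transform applied to
    both, photometric jitter applied to the image only, standardization
    last.  The lesion is guaranteed to remain fully in frame.
    """
    policy = policy or AugPolicy(kind="roi")
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    img = img + rng.uniform(*policy.brightness_range)
    img = img * rng.uniform(*policy.contrast_range)
    shift = _feasible_shift(mask, policy.max_shift, rng)
    img = translate(img, shift)
    mask = translate(mask, shift)
    if rng.random() < policy.flip_prob:
        img = img[:, ::-1]
        mask = mask[:, ::-1]
    return standardize(img), mask


def augment_grade_sample(img: np.ndarray, label: str, rng: np.random.Generator,
                         policy: AugPolicy | None = None):
    """The fourfold grading-policy expansion of one sample.

    Returns a list of exactly four ``(image, label)`` pairs: each a
    random translation of the input, the third and fourth additionally
    flipped horizontally.  Geometry only; no photometric change.
    """
    policy = policy or AugPolicy(kind="grade")
    img = np.asarray(img, dtype=np.float64)
    out = []
    for i in range(4):
        dr = int(rng.integers(-policy.max_shift, policy.max_shift + 1))
        dc = int(rng.integers(-policy.max_shift, policy.max_shift + 1))
        moved = translate(img, (dr, dc))
        if i >= 2:
            moved = moved[:, ::-1]
        out.append((moved, label))
    return out


def expand_grade_dataset(manifest_path, out_dir, seed: int,
                         policy: AugPolicy | None = None):
    """Write the fourfold grading expansion of a dataset to disk.

    Each image ``name.png`` yields ``name_a0.png`` .. ``name_a3.png``
    under ``out_dir/images``; the returned (and written) manifest keeps
    the original labels.  Masks are not carried over: the expansion
    feeds the grading stage only.
    """
    from pathlib import Path

    import pandas as pd

    from . import io as egio

    policy = policy or AugPolicy(kind="grade")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    frame = egio.load_manifest(manifest_path)
    for _, row in frame.iterrows():
        img = egio.read_image(row["image"])
        stem = Path(row["image"]).stem
        for i, (aug, label) in enumerate(augment_grade_sample(img, row["label"], rng, policy)):
            name = f"images/{stem}_a{i}.png"
            egio.write_image(out_dir / name, aug)
            rows.append({"image": name, "mask": "", "label": label})
    expanded = pd.DataFrame(rows, columns=["image", "mask", "label"])
    expanded.to_csv(out_dir / "manifest.csv", index=False)
    return expanded
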