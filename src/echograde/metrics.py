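"""Region- and boundary-similarity metrics and grading evaluation.

Segmentation quality is scored with the Dice similarity coefficient
(DSC), the symmetric Hausdorff distance (HDist) and the average
boundary distance (AvgDist), all in pixel units; grading quality with
per-category accuracy and one-vs-rest ROC AUC.  Contours are the mask
pixels 8-adjacent to background, and both boundary distances are
symmetrized (HDist as the max of the two directed distances, AvgDist as
the mean of the two directed mean nearest-neighbour distances).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import rankdata

GRADE_VALUES = ("3", "4A", "4B", "4C", "5")
GRADE_INDEX = {v: i for i, v in enumerate(GRADE_VALUES)}

__all__ = [
    "GRADE_VALUES",
    "GRADE_INDEX",
    "EvalReport",
    "dice_coefficient",
    "mask_contour",
    "hausdorff_distance",
    "average_boundary_distance",
    "roc_auc_one_vs_rest",
    "per_category_accuracy",
]


def _check_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool)


def dice_coefficient(a, b) -> float:
    """DSC = 2|A ∩ B| / (|A| + |B|).

    Two empty masks agree vacuously (1.0); one empty mask scores 0.
    """
    a = _check_mask(a)
    b = _check_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa = int(a.sum())
    sb = int(b.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def mask_contour(mask) -> np.ndarray:
    """Boundary pixels of a mask: foreground pixels 8-adjacent to background.

    Returns an (n, 2) integer array of (row, col) coordinates.
    """
    mask = _check_mask(mask)
    if not mask.any():
        return np.empty((0, 2), dtype=np.intp)
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), border_value=0
    )
    return np.argwhere(mask & ~interior)


def _check_contour(c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.size == 0:
        raise ValueError("contour is empty")
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError(f"contour must be (n, 2) points, got shape {c.shape}")
    return c


def hausdorff_distance(a, b) -> float:
    """Symmetric Hausdorff distance between two boundary point sets, in px."""
    a = _check_contour(a)
    b = _check_contour(b)
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab = tb.query(a)[0].max()
    d_ba = ta.query(b)[0].max()
    return float(max(d_ab, d_ba))


def average_boundary_distance(a, b) -> float:
    """Mean of the two directed average nearest-neighbour distances, in px."""
    a = _check_contour(a)
    b = _check_contour(b)
    ta, tb = cKDTree(a), cKDTree(b)
    return float(0.5 * (tb.query(a)[0].mean() + ta.query(b)[0].mean()))


def roc_auc_one_vs_rest(scores, labels) -> dict[str, float]:
    """One-vs-rest AUC per grade via the Mann–Whitney rank statistic.

    ``scores`` is (n, 5) with column order matching GRADE_VALUES; ``labels``
    is a sequence of grade strings.  AUC equals P(score_pos > score_neg)
    + 0.5 P(tie).  A grade absent from ``labels`` (or with no negatives)
    has an undefined AUC and is reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([GRADE_INDEX[str(l)] for l in labels])
    if scores.ndim != 2 or scores.shape[1] != len(GRADE_VALUES):
        raise ValueError(f"scores must be (n, {len(GRADE_VALUES)}), got {scores.shape}")
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels length mismatch")
    out: dict[str, float] = {}
    for ci, name in enumerate(GRADE_VALUES):
        pos = labels == ci
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[name] = math.nan
            continue
        ranks = rankdata(scores[:, ci])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        out[name] = float(u / (n_pos * n_neg))
    return out


def per_category_accuracy(pred, truth) -> dict[str, float]:
    """Per-grade accuracy: #correct among truth==c over #truth==c.

    Grades absent from ``truth`` are reported as NaN.
    """
    pred = np.asarray([str(p) for p in pred])
    truth = np.asarray([str(t) for t in truth])
    if pred.shape != truth.shape:
        raise ValueError("pred and truth length mismatch")
    out: dict[str, float] = {}
    for name in GRADE_VALUES:
        sel = truth == name
        n = int(sel.sum())
        out[name] = float((pred[sel] == name).mean()) if n else math.nan
    return out


@dataclasses.dataclass
class EvalReport:
    """Summary of one experiment variant on one evaluation set."""

    variant_name: str
    dsc_mean: float = math.nan
    dsc_sd: float = math.nan
    avgdist_mean: float = math.nan
    avgdist_sd: float = math.nan
    hdist_mean: float = math.nan
    hdist_sd: float = math.nan
    per_category_accuracy: dict[str, float] = dataclasses.field(default_factory=dict)
    auc: dict[str, float] = dataclasses.field(default_factory=dict)
    n_samples: int = 0

    def __post_init__(self):
        for name, value in list(self.per_category_accuracy.items()) + list(self.auc.items()):
            if not math.isnan(value) and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}: ratio {value} outside [0, 1]")
        for value in (self.dsc_mean, self.avgdist_mean, self.hdist_mean):
            if not math.isnan(value) and value < 0:
                raise ValueError("distances and DSC must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_row(self) -> dict:
        row = {
            "variant": self.variant_name,
            "n": self.n_samples,
            "dsc_mean": self.dsc_mean,
            "dsc_sd": self.dsc_sd,
            "avgdist_mean": self.avgdist_mean,
            "avgdist_sd": self.avgdist_sd,
            "hdist_mean": self.hdist_mean,
            "hdist_sd": self.hdist_sd,
        }
        for g in GRADE_VALUES:
            row[f"acc_{g}"] = self.per_category_accuracy.get(g, math.nan)
        for g in GRADE_VALUES:
            row[f"auc_{g}"] = self.auc.get(g, math.nan)
        return row


def write_reports(reports: list[EvalReport], csv_path=None, json_path=None) -> pd.DataFrame:
    """Serialize reports: one CSV row per variant, plus a JSON mirror."""
    frame = pd.DataFrame([r.to_row() for r in reports])
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
    return frame
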