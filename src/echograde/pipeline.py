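"""End-to-end orchestration: splits, variants, ROI hand-off, evaluation.

The full two-stage chain is: identification network -> refinement
(binarize, component filter, Chan-Vese) -> context-preserving ROI crop
-> grading network -> argmax category.  Ablation variants drop pieces
of the chain:

* "Refined ROI-CNN"    - the complete chain (50 Chan-Vese iterations);
* "No Refined ROI-CNN" - binarize + component filter only;
* "No ROI-CNN"         - Chan-Vese alone from a centred-ellipse contour
                          (25% of the frame) with a 1000-iteration cap;
* "One-stage G-CNN"    - the grading network on the whole image.

The ROI hand-off crops the mask's bounding box expanded by a 10% margin
and resizes it to the grading input size, keeping the surrounding
context (texture and boundary carry grading information, so the
background is not masked out).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.transform import resize as sk_resize
from sklearn.model_selection import StratifiedKFold

from . import grade_net as gn
from . import refine as rf
from . import roi_net as rn
from .metrics import (EvalReport, average_boundary_distance, dice_coefficient,
                      hausdorff_distance, mask_contour, per_category_accuracy,
                      roc_auc_one_vs_rest)

VARIANT_NAMES = ("No ROI-CNN", "No Refined ROI-CNN", "Refined ROI-CNN",
                 "One-stage G-CNN")

__all__ = ["VARIANT_NAMES", "ExperimentVariant", "FoldSplit", "PipelineModels",
           "crossval_split", "crossval_evaluate", "extract_roi_patch",
           "identify", "run_pipeline", "evaluate", "make_runner",
           "predictions_table"]


@dataclasses.dataclass(frozen=True)
class ExperimentVariant:
    name: str

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; expected one of {VARIANT_NAMES}")


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    """Stratified fold assignment: ``assignments[i]`` is sample i's fold."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclasses.dataclass
class PipelineModels:
    roi: rn.RoiNet | None = None
    grade: gn.GCnn | None = None


def crossval_split(labels, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k-fold partition of the manifest, reproducible by seed."""
    labels = np.asarray([str(l) for l in labels])
    values, counts = np.unique(labels, return_counts=True)
    short = values[counts < k]
    if short.size:
        raise ValueError(f"classes with fewer than k={k} samples: {list(short)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def extract_roi_patch(img: np.ndarray, mask: np.ndarray, margin: float = 0.1,
                      out_size: int | None = None) -> np.ndarray:
    """Crop the mask's bounding box with a relative margin, then resize.

    The margin expands each side by ``margin`` times the box extent
    along that axis (clipped to the frame); outside-mask context pixels
    are retained.  If ``out_size`` is None the raw crop is returned.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise rf.IdentificationFailure("empty mask: cannot extract ROI patch")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    r0 = max(0, r0 - mr)
    r1 = min(img.shape[0], r1 + mr)
    c0 = max(0, c0 - mc)
    c1 = min(img.shape[1], c1 + mc)
    patch = img[r0:r1, c0:c1]
    if out_size is not None:
        patch = sk_resize(patch, (out_size, out_size), preserve_range=True,
                          anti_aliasing=True)
    return patch


def identify(img: np.ndarray, variant: str, roi_model: rn.RoiNet | None = None,
             cv_params: rf.ChanVeseParams | None = None):
    """Produce the predicted lesion mask (and intermediates) for a variant."""
    ExperimentVariant(variant)
    inter: dict = {}
    if variant == "One-stage G-CNN":
        return None, inter
    if variant == "No ROI-CNN":
        # level-set-only identification: run the full 1000-iteration budget
        # (the centred-ellipse contour starts far from the lesion)
        params = cv_params or rf.ChanVeseParams(max_iter=1000, convergence_tol=0.0)
        init = rf.ellipse_init_mask(img.shape)
        evolved, trace = rf.chan_vese_evolve(img, init, params)
        mask = rf.filter_components(evolved) if evolved.any() else init
        inter.update(init_mask=init, energy_trace=trace)
        return mask, inter
    if roi_model is None:
        raise ValueError(f"variant {variant!r} needs a trained identification network")
    prob = rn.roi_forward(roi_model, img)
    inter["prob_map"] = prob
    rough = rf.binarize(prob)
    if not rough.any():
        raise rf.IdentificationFailure(f"[{variant}] no pixels above threshold")
    if variant == "No Refined ROI-CNN":
        mask = rf.filter_components(rough)
        inter["rough_mask"] = rough
        return mask, inter
    # Refined ROI-CNN
    params = cv_params or rf.ChanVeseParams(max_iter=50)
    mask = rf.refine_roi(prob, img, params)
    inter["rough_mask"] = rough
    return mask, inter


def run_pipeline(img: np.ndarray, models: PipelineModels, variant: str,
                 cv_params: rf.ChanVeseParams | None = None):
    """Classify one image under a variant; returns (grade, intermediates)."""
    img = np.asarray(img, dtype=np.float64)
    if models.grade is None:
        raise ValueError("run_pipeline needs a grading network")
    mask, inter = identify(img, variant, roi_model=models.roi, cv_params=cv_params)
    if mask is None:
        roi_input = sk_resize(img, (models.grade.cfg.input_size,) * 2,
                              preserve_range=True, anti_aliasing=True)
    else:
        inter["pred_mask"] = mask
        roi_input = extract_roi_patch(img, mask, out_size=models.grade.cfg.input_size)
        inter["patch"] = roi_input
    probs = gn.g_forward(models.grade, roi_input)
    inter["probs"] = probs
    return gn.predict_category(probs), inter


def _nanstat(values):
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return math.nan, math.nan
    return float(arr.mean()), float(arr.std())


def evaluate(images, masks, labels, variant_runners) -> list[EvalReport]:
    """Score experiment variants on one evaluation set.

    ``variant_runners`` maps a variant name to a callable
    ``runner(img) -> (pred_mask | None, probs | None)``; identification
    metrics are aggregated when masks are returned, grading metrics when
    probabilities are.  Identification failures score DSC 0 and are
    excluded from the boundary distances.
    """
    reports = []
    labels = [str(l) for l in labels]
    for name, runner in variant_runners.items():
        ExperimentVariant(name)
        dscs, avgs, hds = [], [], []
        all_probs, pred_labels = [], []
        for img, gt in zip(images, masks):
            try:
                pred_mask, probs = runner(np.asarray(img, dtype=np.float64))
            except rf.IdentificationFailure:
                pred_mask, probs = np.zeros_like(np.asarray(gt, bool)), None
            if pred_mask is not None:
                dscs.append(dice_coefficient(pred_mask, gt))
                if pred_mask.any() and np.asarray(gt, bool).any():
                    ca = mask_contour(pred_mask)
                    cb = mask_contour(gt)
                    avgs.append(average_boundary_distance(ca, cb))
                    hds.append(hausdorff_distance(ca, cb))
            if probs is not None:
                all_probs.append(probs)
                pred_labels.append(gn.predict_category(probs))
        report = EvalReport(variant_name=name, n_samples=len(images))
        if dscs:
            report.dsc_mean, report.dsc_sd = _nanstat(dscs)
            report.avgdist_mean, report.avgdist_sd = _nanstat(avgs)
            report.hdist_mean, report.hdist_sd = _nanstat(hds)
        if all_probs:
            report.per_category_accuracy = per_category_accuracy(pred_labels, labels)
            report.auc = roc_auc_one_vs_rest(np.stack(all_probs), labels)
        reports.append(report)
    return reports


def crossval_evaluate(images, masks, labels, split: FoldSplit,
                      runner_factory, variants) -> list[EvalReport]:
    """Cross-validated evaluation: per-fold scores, mean +- sd across folds.

    ``runner_factory(fold, train_indices)`` returns a dict mapping each
    variant name to an ``evaluate``-compatible runner (typically after
    training models on the fold's training indices).  Each variant's
    report aggregates the per-fold mean DSC/distances and per-category
    accuracies/AUCs: the reported mean and sd are across folds.
    """
    labels = [str(l) for l in labels]
    per_fold: dict[str, list[EvalReport]] = {v: [] for v in variants}
    for fold in range(split.k):
        test_idx = split.test_indices(fold)
        runners = runner_factory(fold, split.train_indices(fold))
        fold_reports = evaluate([images[i] for i in test_idx],
                                [masks[i] for i in test_idx],
                                [labels[i] for i in test_idx],
                                {v: runners[v] for v in variants})
        for rep in fold_reports:
            per_fold[rep.variant_name].append(rep)
    out = []
    for name in variants:
        reps = per_fold[name]
        summary = EvalReport(variant_name=name,
                             n_samples=sum(r.n_samples for r in reps))
        summary.dsc_mean, summary.dsc_sd = _nanstat([r.dsc_mean for r in reps])
        summary.avgdist_mean, summary.avgdist_sd = _nanstat([r.avgdist_mean for r in reps])
        summary.hdist_mean, summary.hdist_sd = _nanstat([r.hdist_mean for r in reps])
        from .metrics import GRADE_VALUES
        for field in ("per_category_accuracy", "auc"):
            merged = {}
            for g in GRADE_VALUES:
                vals = [getattr(r, field).get(g, math.nan) for r in reps
                        if getattr(r, field)]
                merged[g], _ = _nanstat(vals) if vals else (math.nan, math.nan)
            setattr(summary, field, merged)
        out.append(summary)
    return out


def predictions_table(images, names, models: PipelineModels, variant: str,
                      cv_params: rf.ChanVeseParams | None = None):
    """Per-image grading probabilities as a DataFrame.

    Columns: image, prob_3 .. prob_5, predicted_label, variant.
    """
    import pandas as pd

    from .metrics import GRADE_VALUES
    rows = []
    for img, name in zip(images, names):
        label, inter = run_pipeline(np.asarray(img, float), models, variant,
                                    cv_params=cv_params)
        row = {"image": name}
        row.update({f"prob_{g}": p for g, p in zip(GRADE_VALUES, inter["probs"])})
        row["predicted_label"] = label
        row["variant"] = variant
        rows.append(row)
    return pd.DataFrame(rows)


def make_runner(models: PipelineModels, variant: str,
                cv_params: rf.ChanVeseParams | None = None):
    """Build an ``evaluate``-compatible runner from trained models."""

    def runner(img):
        if models.grade is None:
            mask, _ = identify(img, variant, roi_model=models.roi, cv_params=cv_params)
            return mask, None
        label, inter = run_pipeline(img, models, variant, cv_params=cv_params)
        return inter.get("pred_mask"), inter["probs"]

    return runner
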