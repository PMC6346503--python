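"""Scaled-down phantom studies exercising the full pipeline.

These drivers reproduce the design of the reference experiments at desk
scale: 96-px phantoms, reduced filter counts, and short SGD schedules,
so a complete identification + grading study runs on one CPU in
minutes.  Each study takes a single integer seed that controls phantom
generation, initialization and minibatch order end to end.

Study sizes (the package's own scaled conditions): 200 phantoms
(160/40 train/test) for identification recovery, 250 fresh phantoms for
the identification-variant ordering, 100 phantoms per grade for the
5-category grading study and 100 per grade for the extreme binary
(grade 3 vs 5) task.
"""

from __future__ import annotations

import numpy as np

from . import grade_net as gn
from . import phantom as ph
from . import pipeline as pl
from . import refine as rf
from . import roi_net as rn
from .augment import standardize
from .metrics import dice_coefficient, per_category_accuracy, roc_auc_one_vs_rest

SIZE = 96

__all__ = ["tiny_roi_config", "tiny_g_config", "roi_recovery_study",
           "variant_ordering_study", "grading_study", "binary_grading_study"]


def tiny_roi_config(seed: int = 0) -> rn.RoiNetConfig:
    return rn.RoiNetConfig(input_size=SIZE, base_filters=8,
                           transitional_filters=32, seed=seed)


def tiny_g_config(seed: int = 0) -> gn.GNetConfig:
    return gn.GNetConfig(input_size=SIZE, base_filters=8,
                         fc_sizes=(64, 32, 5), seed=seed)


def _phantom_bank(n_per_grade: int, seed: int, shuffle_seed: int):
    grades = [g for g in ph.GRADE_VALUES for _ in range(n_per_grade)]
    imgs, masks, labels = ph.render_batch(grades, seed=seed, size=SIZE)
    labels = np.asarray(labels)
    perm = np.random.default_rng(shuffle_seed).permutation(len(labels))
    return imgs[perm], masks[perm], labels[perm]


def roi_recovery_study(seed: int, n_per_grade: int = 40, epochs: int = 10):
    """Train the identification net on 200 phantoms; score a held-out fifth.

    Returns the trained net and mean held-out DSC before (binarize +
    component filter) and after Chan-Vese refinement.
    """
    imgs, masks, labels = _phantom_bank(n_per_grade, seed + 11, seed + 12)
    n_test = len(imgs) // 5
    tr = slice(0, len(imgs) - n_test)
    te = slice(len(imgs) - n_test, None)
    net = rn.build_roi_net(tiny_roi_config(seed))
    tcfg = rn.TrainConfig(epochs=epochs, learning_rate=0.05, batch_size=16,
                          seed=seed)
    history = rn.train_roi_net(net, (list(imgs[tr]), list(masks[tr])), tcfg)
    params = rf.ChanVeseParams(max_iter=50)
    unrefined, refined = [], []
    for img, gt in zip(imgs[te], masks[te]):
        prob = rn.roi_forward(net, img)
        rough = rf.binarize(prob)
        if not rough.any():
            unrefined.append(0.0)
            refined.append(0.0)
            continue
        unrefined.append(dice_coefficient(rf.filter_components(rough), gt))
        refined.append(dice_coefficient(rf.refine_roi(prob, img, params), gt))
    return {
        "net": net,
        "history": history,
        "dsc_unrefined": float(np.mean(unrefined)),
        "dsc_refined": float(np.mean(refined)),
        "n_train": len(imgs) - n_test,
        "n_test": n_test,
    }


def variant_ordering_study(roi_model: rn.RoiNet, seed: int, n: int = 250):
    """Mean DSC of the three identification variants on fresh phantoms."""
    per_grade = int(np.ceil(n / len(ph.GRADE_VALUES)))
    imgs, masks, _ = _phantom_bank(per_grade, seed + 21, seed + 22)
    imgs, masks = imgs[:n], masks[:n]
    dscs = {name: [] for name in ("Refined ROI-CNN", "No Refined ROI-CNN",
                                  "No ROI-CNN")}
    for img, gt in zip(imgs, masks):
        for name in dscs:
            try:
                mask, _ = pl.identify(img, name, roi_model=roi_model)
            except rf.IdentificationFailure:
                mask = np.zeros_like(gt)
            dscs[name].append(dice_coefficient(mask, gt))
    return {name: float(np.mean(v)) for name, v in dscs.items()} | {"n": n}


def _train_grader(inputs, labels, seed: int, epochs: int):
    net = gn.build_g_cnn(tiny_g_config(seed))
    tcfg = rn.TrainConfig(epochs=epochs, learning_rate=0.03, lr_decay=0.9,
                          batch_size=16, seed=seed)
    gn.train_g_cnn(net, (inputs, labels), tcfg)
    return net


def _accuracy(net, inputs, labels):
    x = np.stack([standardize(p) for p in inputs]).astype(np.float32)
    probs = net.forward_probs(x)
    pred = [gn.predict_category(p) for p in probs]
    return (float(np.mean([p == t for p, t in zip(pred, labels)])),
            per_category_accuracy(pred, labels),
            roc_auc_one_vs_rest(probs, labels))


def grading_study(roi_model: rn.RoiNet, seed: int, n_per_grade: int = 100,
                  epochs: int = 6):
    """Two-stage (refined ROI -> G-CNN) vs one-stage whole-image grading.

    Both graders share the architecture, schedule and seed; they differ
    only in their input: refinement-produced ROI patches versus the
    whole image.  Returns held-out accuracies and per-category detail.
    """
    imgs, masks, labels = _phantom_bank(n_per_grade, seed + 31, seed + 32)
    n_test = len(imgs) // 5
    split = len(imgs) - n_test
    patches = []
    for img in imgs:
        try:
            mask, _ = pl.identify(img, "Refined ROI-CNN", roi_model=roi_model)
            patches.append(pl.extract_roi_patch(img, mask, out_size=SIZE))
        except rf.IdentificationFailure:
            patches.append(img)
    two_stage = _train_grader(patches[:split], list(labels[:split]), seed, epochs)
    one_stage = _train_grader(list(imgs[:split]), list(labels[:split]), seed, epochs)
    acc2, per2, auc2 = _accuracy(two_stage, patches[split:], labels[split:])
    acc1, per1, auc1 = _accuracy(one_stage, list(imgs[split:]), labels[split:])
    return {
        "two_stage_net": two_stage,
        "one_stage_net": one_stage,
        "two_stage_accuracy": acc2,
        "one_stage_accuracy": acc1,
        "two_stage_per_category": per2,
        "one_stage_per_category": per1,
        "two_stage_auc": auc2,
        "n_train": split,
        "n_test": n_test,
    }


def binary_grading_study(seed: int, n_per_class: int = 100, epochs: int = 4):
    """Extreme-task recovery: smooth ovals (grade 3) vs spiculated (grade 5).

    The grader sees ground-truth ROI patches, isolating the grading
    network from identification error.
    """
    grades = ["3"] * n_per_class + ["5"] * n_per_class
    imgs, masks, labels = ph.render_batch(grades, seed=seed + 41, size=SIZE)
    labels = np.asarray(labels)
    perm = np.random.default_rng(seed + 42).permutation(len(labels))
    imgs, masks, labels = imgs[perm], masks[perm], labels[perm]
    patches = [pl.extract_roi_patch(i, m, out_size=SIZE)
               for i, m in zip(imgs, masks)]
    n_test = len(imgs) // 5
    split = len(imgs) - n_test
    net = _train_grader(patches[:split], list(labels[:split]), seed, epochs)
    acc, per_cat, _ = _accuracy(net, patches[split:], labels[split:])
    return {"net": net, "accuracy": acc, "per_category": per_cat,
            "n_train": split, "n_test": n_test}
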