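"""Region/boundary metrics against brute-force oracles and hand counts."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from echograde import metrics as mx


def brute_dice(a, b):
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def brute_hausdorff(a, b):
    d_ab = max(min(math.dist(p, q) for q in b) for p in a)
    d_ba = max(min(math.dist(p, q) for q in a) for p in b)
    return max(d_ab, d_ba)


def brute_avgdist(a, b):
    d_ab = np.mean([min(math.dist(p, q) for q in b) for p in a])
    d_ba = np.mean([min(math.dist(p, q) for q in a) for p in b])
    return 0.5 * (d_ab + d_ba)


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        b = np.zeros((8, 8), bool)
        b[6:8, 6:8] = True
        assert mx.dice_coefficient(a, a) == 1.0
        assert mx.dice_coefficient(a, b) == 0.0

    def test_half_overlap_shifted_square(self):
        a = np.zeros((20, 30), bool)
        a[5:15, 5:15] = True
        b = np.zeros((20, 30), bool)
        b[5:15, 10:20] = True  # shifted 5 columns: |A|=|B|=100, overlap 50
        assert mx.dice_coefficient(a, b) == pytest.approx(0.5)

    def test_empty_conventions(self):
        empty = np.zeros((5, 5), bool)
        full = np.ones((5, 5), bool)
        assert mx.dice_coefficient(empty, empty) == 1.0
        assert mx.dice_coefficient(empty, full) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mx.dice_coefficient(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_matches_pixel_set_oracle_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.random((16, 16)) < 0.3
            b = rng.random((16, 16)) < 0.3
            d = mx.dice_coefficient(a, b)
            assert d == pytest.approx(brute_dice(a, b), abs=1e-12)
            assert d == mx.dice_coefficient(b, a)


class TestBoundaryDistances:
    def test_single_point_pairs(self):
        a = np.array([[0, 0]])
        b = np.array([[3, 4]])
        assert mx.hausdorff_distance(a, b) == pytest.approx(5.0)
        assert mx.average_boundary_distance(a, b) == pytest.approx(5.0)

    def test_directed_asymmetry_resolved_by_max(self):
        a = np.array([[0, 0], [0, 10]])
        b = np.array([[0, 0]])
        assert mx.hausdorff_distance(a, b) == pytest.approx(10.0)

    def test_avgdist_mean_of_directed_means(self):
        a = np.array([[0, 0], [0, 2]])
        b = np.array([[0, 1]])
        # directed means: (1+1)/2 = 1 and 1 -> symmetric mean 1
        assert mx.average_boundary_distance(a, b) == pytest.approx(1.0)

    def test_identical_contours_are_zero(self):
        c = np.array([[1, 2], [3, 4], [5, 6]])
        assert mx.hausdorff_distance(c, c) == 0.0
        assert mx.average_boundary_distance(c, c) == 0.0

    def test_empty_contour_raises(self):
        with pytest.raises(ValueError):
            mx.hausdorff_distance(np.empty((0, 2)), np.array([[0, 0]]))
        with pytest.raises(ValueError):
            mx.average_boundary_distance(np.array([[0, 0]]), np.empty((0, 2)))

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 30, size=(rng.integers(1, 50), 2))
            b = rng.integers(0, 30, size=(rng.integers(1, 50), 2))
            assert mx.hausdorff_distance(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-9)
            assert mx.average_boundary_distance(a, b) == pytest.approx(brute_avgdist(a, b), abs=1e-9)

    def test_hausdorff_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            pts = [rng.integers(0, 20, size=(rng.integers(2, 15), 2)) for _ in range(3)]
            dab = mx.hausdorff_distance(pts[0], pts[1])
            dbc = mx.hausdorff_distance(pts[1], pts[2])
            dac = mx.hausdorff_distance(pts[0], pts[2])
            assert dac <= dab + dbc + 1e-9


class TestContour:
    def test_contour_is_eight_adjacent_boundary(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        contour = {tuple(p) for p in mx.mask_contour(mask)}
        # a 3x3 square's interior is only its centre pixel
        expected = {(r, c) for r in range(2, 5) for c in range(2, 5)} - {(3, 3)}
        assert contour == expected

    def test_points_inside_grid(self, small_phantoms):
        images, masks, _ = small_phantoms
        for m in masks[:5]:
            pts = mx.mask_contour(m)
            assert pts[:, 0].min() >= 0 and pts[:, 0].max() < m.shape[0]
            assert pts[:, 1].min() >= 0 and pts[:, 1].max() < m.shape[1]


class TestAuc:
    def _scores(self, col, values, n):
        s = np.full((n, 5), 0.1)
        s[:, col] = values
        return s

    def test_perfect_separation_and_ties(self):
        labels = ["3", "3", "4A", "4A"]
        s = self._scores(0, [0.9, 0.8, 0.2, 0.1], 4)
        assert mx.roc_auc_one_vs_rest(s, labels)["3"] == 1.0
        s = self._scores(0, [0.5, 0.5, 0.5, 0.5], 4)
        assert mx.roc_auc_one_vs_rest(s, labels)["3"] == 0.5

    def test_concordant_pair_count(self):
        labels = ["3", "3", "4A", "4A"]
        s = self._scores(0, [0.9, 0.4, 0.6, 0.1], 4)
        assert mx.roc_auc_one_vs_rest(s, labels)["3"] == pytest.approx(0.75)

    def test_single_class_flagged_nan(self):
        labels = ["3", "3", "3"]
        s = np.random.default_rng(0).random((3, 5))
        out = mx.roc_auc_one_vs_rest(s, labels)
        assert math.isnan(out["4A"])
        assert math.isnan(out["3"])  # no negatives either

    def test_rank_formula_matches_trapezoidal_roc(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 40
            labels = rng.choice(["3", "4A", "4B", "4C", "5"], size=n)
            scores = rng.random((n, 5))
            scores[np.arange(n), [mx.GRADE_INDEX[l] for l in labels]] += rng.random(n)
            ours = mx.roc_auc_one_vs_rest(scores, labels)
            for g, ci in mx.GRADE_INDEX.items():
                y = (labels == g).astype(int)
                if 0 < y.sum() < n:
                    assert ours[g] == pytest.approx(roc_auc_score(y, scores[:, ci]), abs=1e-9)


class TestPerCategoryAccuracy:
    def test_perfect_and_all_wrong(self):
        truth = ["3", "4A", "4B", "4C", "5"]
        assert all(v == 1.0 for v in mx.per_category_accuracy(truth, truth).values())
        wrong = ["4A", "4B", "4C", "5", "3"]
        assert all(v == 0.0 for v in mx.per_category_accuracy(wrong, truth).values())

    def test_hand_count(self):
        truth = ["3", "3", "4A", "5"]
        pred = ["3", "4A", "4A", "5"]
        acc = mx.per_category_accuracy(pred, truth)
        assert acc["3"] == 0.5
        assert acc["4A"] == 1.0
        assert acc["5"] == 1.0
        assert math.isnan(acc["4B"])


class TestEvalReport:
    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            mx.EvalReport("x", per_category_accuracy={"3": 1.5})

    def test_serialization_roundtrip(self, tmp_path):
        rep = mx.EvalReport("Refined ROI-CNN", dsc_mean=0.9, dsc_sd=0.01,
                            per_category_accuracy={g: 0.8 for g in mx.GRADE_VALUES},
                            auc={g: 0.9 for g in mx.GRADE_VALUES}, n_samples=10)
        frame = mx.write_reports([rep], csv_path=tmp_path / "r.csv",
                                 json_path=tmp_path / "r.json")
        assert len(frame) == 1
        import json
        import pandas as pd
        back = pd.read_csv(tmp_path / "r.csv")
        assert back.loc[0, "dsc_mean"] == pytest.approx(0.9)
        data = json.loads((tmp_path / "r.json").read_text())
        assert data[0]["variant_name"] == "Refined ROI-CNN"
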