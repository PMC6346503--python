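"""Refinement: thresholding, the 40%-area filter, Chan-Vese evolution."""

import numpy as np
import pytest
from scipy import ndimage

from echograde import metrics as mx
from echograde import refine as rf
from tests.conftest import make_disk


class TestBinarize:
    def test_conventions(self):
        assert not rf.binarize(np.zeros((4, 4))).any()
        gt = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.array_equal(rf.binarize(gt), gt.astype(bool))
        assert rf.binarize(np.full((3, 3), 0.5), 0.5).all()  # >= at the boundary

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            rf.binarize(np.zeros((2, 2)), threshold=0.0)


class TestFilterComponents:
    def test_single_component_unchanged(self):
        m = make_disk(64, (32, 32), 10)
        assert np.array_equal(rf.filter_components(m), m)

    def test_forty_percent_area_rule(self):
        m = np.zeros((40, 40), bool)
        m[2:12, 2:12] = True          # area 100
        m[25:31, 25:30] = True        # area 30 < 40% of 100 -> removed
        out = rf.filter_components(m)
        assert out[2:12, 2:12].all() and not out[25:31, 25:30].any()

    def test_survivors_resolved_by_centre_distance(self):
        m = np.zeros((40, 40), bool)
        m[0:10, 0:10] = True          # area 100, corner
        m[17:23, 16:26] = True        # area 60, centred; 60 >= 40 -> survives
        out = rf.filter_components(m)
        assert out[17:23, 16:26].all() and not out[0:10, 0:10].any()

    def test_output_always_single_component(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.random((48, 48)) < 0.35
            m = ndimage.binary_opening(m)
            if not m.any():
                continue
            out = rf.filter_components(m)
            _, n = ndimage.label(out, structure=np.ones((3, 3)))
            assert n == 1

    def test_empty_mask_is_identification_failure(self):
        with pytest.raises(rf.IdentificationFailure):
            rf.filter_components(np.zeros((8, 8), bool))


def two_level_image(size=96, radius=20, inside=0.0, outside=1.0):
    disk = make_disk(size, (size // 2, size // 2), radius)
    return np.where(disk, inside, outside), disk


class TestEnergy:
    def test_zero_on_true_boundary_without_length_term(self):
        img, disk = two_level_image()
        params = rf.ChanVeseParams(alpha=0.0)
        assert rf.chan_vese_energy(img, disk, params) == pytest.approx(0.0)

    def test_whole_frame_contour_closed_form(self):
        # equal-area two-level image, contour = full frame: c1 = 0.5,
        # residual = N * 0.25 (no outside region, no boundary edges)
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        params = rf.ChanVeseParams(alpha=0.0)
        e = rf.chan_vese_energy(img, np.ones((10, 10), bool), params)
        assert e == pytest.approx(100 * 0.25)

    def test_alpha_adds_contour_length_exactly(self):
        img, disk = two_level_image()
        square = np.zeros_like(disk)
        square[40:56, 40:56] = True  # 16x16 square: 4-edge boundary length 64
        e0 = rf.chan_vese_energy(img, square, rf.ChanVeseParams(alpha=0.0))
        e1 = rf.chan_vese_energy(img, square, rf.ChanVeseParams(alpha=2.0))
        assert e1 - e0 == pytest.approx(2.0 * 64)

    def test_state_carries_region_means(self):
        img, disk = two_level_image(inside=0.2, outside=0.8)
        state = rf.chan_vese_state(img, disk, rf.ChanVeseParams())
        assert state.c1 == pytest.approx(0.2)
        assert state.c2 == pytest.approx(0.8)
        assert np.array_equal(state.mask, disk)


class TestEvolve:
    def test_dilated_init_recovers_disk_within_iteration_cap(self):
        img, disk = two_level_image()
        init = ndimage.binary_dilation(disk, iterations=5)
        final, trace = rf.chan_vese_evolve(img, init, rf.ChanVeseParams(max_iter=50))
        assert mx.dice_coefficient(final, disk) >= 0.99
        assert len(trace) - 1 <= 50
        assert trace[-1] <= trace[0]
        assert abs(img[final].mean() - 0.0) < 1e-3
        assert abs(img[~final].mean() - 1.0) < 1e-3

    def test_exact_init_is_near_fixed_point(self):
        img, disk = two_level_image()
        final, _ = rf.chan_vese_evolve(img, disk, rf.ChanVeseParams(max_iter=50))
        assert mx.dice_coefficient(final, disk) >= 0.99

    def test_eroded_init_grows_back(self):
        img, disk = two_level_image()
        init = ndimage.binary_erosion(disk, iterations=5)
        final, _ = rf.chan_vese_evolve(img, init, rf.ChanVeseParams(max_iter=50))
        assert mx.dice_coefficient(final, disk) >= 0.99

    def test_agrees_with_skimage_reference(self):
        from skimage.segmentation import chan_vese as sk_chan_vese
        img, disk = two_level_image()
        init = ndimage.binary_dilation(disk, iterations=5)
        ours, _ = rf.chan_vese_evolve(img, init, rf.ChanVeseParams(max_iter=50))
        theirs = sk_chan_vese(img, mu=0.1, lambda1=1, lambda2=1, max_num_iter=200,
                              init_level_set=init.astype(float) * 2 - 1)
        assert mx.dice_coefficient(ours, theirs) >= 0.98

    def test_empty_init_raises(self):
        img, _ = two_level_image()
        with pytest.raises(rf.IdentificationFailure):
            rf.chan_vese_evolve(img, np.zeros_like(img, dtype=bool), rf.ChanVeseParams())

    def test_vanishing_contour_returns_init_with_warning(self):
        # uniform image: inside mean == outside mean, curvature shrinks the
        # tiny region until it disappears
        img = np.full((48, 48), 0.5)
        init = make_disk(48, (24, 24), 2)
        with pytest.warns(UserWarning, match="vanished"):
            out, _ = rf.chan_vese_evolve(img, init, rf.ChanVeseParams(max_iter=400, alpha=5.0))
        assert np.array_equal(out, init)


class TestRefineRoi:
    def test_spurious_blob_removed_and_boundary_recovered(self):
        img, disk = two_level_image()
        prob = np.where(ndimage.binary_dilation(disk, iterations=3), 0.9, 0.05)
        prob[5:10, 5:10] = 0.95  # small spurious blob, area << 40% of main
        out = rf.refine_roi(prob, img, rf.ChanVeseParams(max_iter=50))
        assert not out[5:10, 5:10].any()
        assert mx.dice_coefficient(out, disk) >= 0.99

    def test_empty_probability_map_fails_loudly(self):
        img, _ = two_level_image()
        with pytest.raises(rf.IdentificationFailure):
            rf.refine_roi(np.zeros_like(img), img, rf.ChanVeseParams())

    def test_idempotent_in_the_limit(self):
        img, disk = two_level_image()
        prob = np.where(ndimage.binary_dilation(disk, iterations=4), 0.9, 0.1)
        once = rf.refine_roi(prob, img, rf.ChanVeseParams(max_iter=50))
        twice = rf.refine_roi(once.astype(float), img, rf.ChanVeseParams(max_iter=50))
        assert abs(mx.dice_coefficient(once, disk) - mx.dice_coefficient(twice, disk)) < 0.02

    def test_ellipse_init_covers_quarter_frame(self):
        m = rf.ellipse_init_mask((96, 96), 0.25)
        assert abs(m.mean() - 0.25) < 0.02
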