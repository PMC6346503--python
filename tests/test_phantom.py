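"""Phantom generator: morphology encoding, speckle statistics, reproducibility."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from echograde import io as egio
from echograde import metrics as mx
from echograde import phantom as ph
from tests.conftest import make_disk


class TestSpecSampling:
    def test_grade3_is_smooth_oval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = ph.sample_phantom_spec("3", rng, size=96)
            assert spec.spicule_count == 0
            assert spec.irregularity_amp <= 0.05

    def test_grade5_is_highly_irregular(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = ph.sample_phantom_spec("5", rng, size=96)
            assert spec.spicule_count >= 6
            assert spec.irregularity_amp >= 0.35

    def test_unknown_grade_raises(self):
        with pytest.raises(ValueError):
            ph.sample_phantom_spec("2", np.random.default_rng(0))

    def test_same_seed_same_spec(self):
        s1 = ph.sample_phantom_spec("4B", np.random.default_rng(5), size=96)
        s2 = ph.sample_phantom_spec("4B", np.random.default_rng(5), size=96)
        assert s1 == s2

    def test_mean_irregularity_strictly_increases_with_grade(self):
        rng = np.random.default_rng(1)
        means = []
        for g in ph.GRADE_VALUES:
            amps = [ph.sample_phantom_spec(g, rng, size=288).irregularity_amp
                    for _ in range(1000)]
            means.append(np.mean(amps))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_spicule_count_non_decreasing_with_grade(self):
        rng = np.random.default_rng(2)
        means = []
        for g in ph.GRADE_VALUES:
            means.append(np.mean([ph.sample_phantom_spec(g, rng, size=288).spicule_count
                                  for _ in range(300)]))
        assert all(a <= b for a, b in zip(means, means[1:]))


class TestRender:
    def test_deterministic_bit_identical(self):
        spec = ph.sample_phantom_spec("4C", np.random.default_rng(3), size=96)
        img1, mask1, g1 = ph.render_phantom(spec)
        img2, mask2, g2 = ph.render_phantom(spec)
        assert np.array_equal(img1, img2) and np.array_equal(mask1, mask2)
        assert g1 == g2 == "4C"

    def test_smooth_spec_renders_near_analytic_ellipse(self):
        spec = ph.PhantomSpec(grade="3", center=(48.0, 48.0), base_radii=(18.0, 12.0),
                              irregularity_amp=0.0, spicule_count=0,
                              lesion_contrast=0.3, speckle_scale=0.25, seed=11, size=96)
        _, mask, _ = ph.render_phantom(spec)
        yy, xx = np.mgrid[0:96, 0:96]
        analytic = ((yy - 48.0) / 18.0) ** 2 + ((xx - 48.0) / 12.0) ** 2 <= 1.0
        assert mx.dice_coefficient(mask, analytic) >= 0.98

    def test_speckle_is_rayleigh_before_smoothing(self):
        # Rayleigh mean/std ratio = sqrt(pi/2)/sqrt(2 - pi/2) ~ 1.91
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(100):
            spec = ph.sample_phantom_spec("3", rng, size=96)
            img, mask, _ = ph.render_phantom(spec, smooth_sigma=0.0)
            bg = img[~mask]
            bg = bg[bg < 1.0]  # exclude clipped tail
            ratios.append(bg.mean() / bg.std())
        assert 1.7 <= np.mean(ratios) <= 2.1

    def test_lesion_is_hypoechoic(self, small_phantoms):
        images, masks, _ = small_phantoms
        for img, mask in zip(images, masks):
            assert img[mask].mean() < img[~mask].mean()

    def test_masks_are_single_components_inside_frame(self, small_phantoms):
        _, masks, _ = small_phantoms
        for m in masks:
            assert ph.is_single_component(m)
            border = np.concatenate([m[0], m[-1], m[:, 0], m[:, -1]])
            assert not border.any()

    def test_escaping_lesion_rejected(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(grade="3", center=(10.0, 48.0), base_radii=(18.0, 12.0),
                           irregularity_amp=0.0, spicule_count=0,
                           lesion_contrast=0.3, speckle_scale=0.25, seed=0, size=96)

    def test_distractor_streaks_brighten_background_only(self):
        rng = np.random.default_rng(6)
        base = ph.sample_phantom_spec("3", rng, size=96)
        with_streaks = ph.PhantomSpec(**{**base.__dict__, "n_distractors": 3})
        img0, mask0, _ = ph.render_phantom(base)
        img1, mask1, _ = ph.render_phantom(with_streaks)
        assert np.array_equal(mask0, mask1)  # lesion geometry untouched
        assert img1[~mask1].mean() > img0[~mask0].mean()
        assert np.allclose(img1[mask1], img0[mask0])  # hypoechoic interior kept

    def test_compactness_recovers_grade_ordering(self):
        rng = np.random.default_rng(5)
        means = []
        for g in ph.GRADE_VALUES:
            vals = []
            for _ in range(60):
                spec = ph.sample_phantom_spec(g, rng, size=96)
                _, mask, _ = ph.render_phantom(spec)
                vals.append(ph.shape_compactness(mask))
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


def _tree_hash(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestDataset:
    def test_manifest_counts_and_contents(self, tmp_path):
        frame = ph.generate_dataset(2, tmp_path / "d", seed=9, size=96)
        assert len(frame) == 10
        assert frame["label"].value_counts().to_dict() == {g: 2 for g in ph.GRADE_VALUES}
        loaded = egio.load_manifest(tmp_path / "d" / "manifest.csv")
        for _, row in loaded.iterrows():
            mask = egio.read_mask(row["mask"])
            assert mask.any()
            border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
            assert not border.any()

    def test_regeneration_is_byte_identical(self, tmp_path):
        ph.generate_dataset(1, tmp_path / "a", seed=21, size=96)
        ph.generate_dataset(1, tmp_path / "b", seed=21, size=96)
        assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")
        ph.generate_dataset(1, tmp_path / "c", seed=22, size=96)
        assert _tree_hash(tmp_path / "a") != _tree_hash(tmp_path / "c")

    def test_clinical_ratio_preset(self, tmp_path):
        frame = ph.generate_dataset(20, tmp_path / "d", seed=1, size=96, ratios="clinical")
        counts = frame["label"].value_counts()
        # proportions follow the clinical case counts: 4C most, 5 fewest
        assert counts["4C"] == counts.max()
        assert counts["5"] == counts.min()

    def test_png_roundtrip_lossless_mask(self, tmp_path):
        mask = make_disk()
        egio.write_mask(tmp_path / "m.png", mask)
        assert np.array_equal(egio.read_mask(tmp_path / "m.png"), mask)
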