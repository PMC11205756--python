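"""Counting-chamber image pipeline on constructed and generated fields."""

import numpy as np
import pytest

from algadens import (
    CountingConfig,
    SceneConfig,
    analyze_particles,
    count_pipeline,
    counts_to_concentration,
    subtract_background,
    synth_scene,
    threshold_mask,
    to_8bit,
)
from algadens.cellcount import ImageError


class TestSubtractBackground:
    def test_uniform_image_maps_to_near_constant(self):
        img = np.full((64, 64), 0.7)
        out = subtract_background(img, radius=10)
        assert np.ptp(out) < 1.0 / 255.0

    def test_ramp_removed_contrast_preserved(self):
        # border strips (one structuring radius wide) keep an edge
        # artifact, as any morphological background estimate does; the
        # suppression claim holds on the interior
        rows, cols = np.mgrid[0:128, 0:128].astype(float)
        ramp = 0.2 * cols / 127
        img = 0.6 + ramp
        img[40:50, 40:50] -= 0.3  # dark square "cell"
        out = subtract_background(img, radius=20)[20:-20, 20:-20]
        background = out[np.abs(out) < 0.15]
        assert np.ptp(background) <= 0.1 * 0.2  # ramp reduced >= 90%
        depth = out[24, 24] - np.median(background)
        assert depth == pytest.approx(-0.3, rel=0.1)

    def test_rgb_rejected(self):
        with pytest.raises(ImageError):
            subtract_background(np.zeros((10, 10, 3)))


class TestTo8Bit:
    def test_full_range_survives(self):
        img = np.array([[0.0, 255.0], [128.0, 64.0]])
        out = to_8bit(img)
        assert out.dtype == np.uint8
        np.testing.assert_array_equal(out, img.astype(np.uint8))

    def test_unit_interval_scaled(self):
        out = to_8bit(np.array([[0.0, 0.5, 1.0]]))
        np.testing.assert_array_equal(out, [[0, 128, 255]])

    def test_constant_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = to_8bit(np.full((4, 4), 3.3))
        assert out.max() == 0


class TestThreshold:
    def test_all_bright_empty_mask(self):
        img = np.full((8, 8), 255, dtype=np.uint8)
        assert not threshold_mask(img, 0, 200).any()

    def test_all_dark_full_mask(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        assert threshold_mask(img, 0, 200).all()

    def test_partition(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 255
        mask = threshold_mask(img, 0, 200)
        assert mask[:, :4].all() and not mask[:, 4:].any()

    def test_bad_bounds(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ImageError):
            threshold_mask(img, 10, 300)


class TestAnalyzeParticles:
    def test_empty_mask(self):
        assert analyze_particles(np.zeros((16, 16), bool)) == []

    def test_solid_square_counted_with_area(self):
        mask = np.zeros((32, 32), bool)
        mask[5:15, 5:15] = True
        particles = analyze_particles(mask, 6, 150)
        assert len(particles) == 1
        assert particles[0].area == 100

    def test_speck_excluded_by_min_area(self):
        mask = np.zeros((64, 64), bool)
        mask[5:13, 5:15] = True     # 80 px
        mask[30:38, 30:40] = True   # 80 px
        mask[50, 50] = True
        mask[50, 51] = True
        mask[51, 50] = True         # 3 px speck
        assert len(analyze_particles(mask, 6, 150)) == 2

    def test_size_filter_monotonicity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((128, 128)) < 0.2
        narrow = len(analyze_particles(mask, 6, 50))
        wide = len(analyze_particles(mask, 3, 150))
        assert wide >= narrow

    def test_border_exclusion_switch(self):
        mask = np.zeros((20, 20), bool)
        mask[0:4, 0:4] = True
        assert len(analyze_particles(mask, 6, 150)) == 1
        assert len(analyze_particles(mask, 6, 150, exclude_border=True)) == 0


class TestConcentration:
    def test_zero_count(self):
        assert counts_to_concentration(0, CountingConfig()) == 0.0

    def test_unit_arithmetic(self):
        cfg = CountingConfig(analyzed_area=0.64, chamber_depth=0.1,
                             dilution_factor=1.0)
        assert counts_to_concentration(100, cfg) == pytest.approx(1.5625e9)

    def test_dilution_scales_linearly(self):
        c1 = counts_to_concentration(50, CountingConfig(dilution_factor=1))
        c2 = counts_to_concentration(50, CountingConfig(dilution_factor=2))
        assert c2 == pytest.approx(2 * c1)

    def test_invalid_config(self):
        with pytest.raises(ImageError):
            CountingConfig(analyzed_area=0.0)
        with pytest.raises(ImageError):
            CountingConfig(threshold_lo=201, threshold_hi=200)
        with pytest.raises(ImageError):
            CountingConfig(min_area=0)


class TestPipeline:
    def test_blank_field_counts_zero(self):
        img, _ = synth_scene(SceneConfig(seed=10, n_cells=0))
        with pytest.warns(UserWarning, match="no separable"):
            assert count_pipeline(img).count == 0

    def test_recovers_fifty_disks(self):
        img, truth = synth_scene(SceneConfig(seed=3, n_cells=50))
        res = count_pipeline(img)
        assert res.count == truth["n_cells"]
        assert res.cells_per_liter == pytest.approx(50 / 6.4e-8)

    def test_specks_do_not_inflate_count(self):
        img, truth = synth_scene(SceneConfig(seed=4, n_cells=50, noise_sd=0.0))
        rng = np.random.default_rng(4)
        for _ in range(5):  # sub-min-area specks, clear of the margin
            r, c = rng.integers(10, img.shape[0] - 10, size=2)
            img[r, c] -= 0.45
        assert count_pipeline(img).count == 50

    def test_translation_invariance(self):
        cfg = SceneConfig(seed=6, n_cells=30, noise_sd=0.0, ramp_amplitude=0.0)
        img, _ = synth_scene(cfg)
        shifted = np.roll(img, shift=(7, -5), axis=(0, 1))
        assert count_pipeline(img).count == count_pipeline(shifted).count == 30

    def test_result_consistency(self):
        img, _ = synth_scene(SceneConfig(seed=5, n_cells=20))
        res, inter = count_pipeline(img, return_intermediates=True)
        assert res.count == len(res.particle_areas) == len(inter["particles"])
        assert inter["image_8bit"].dtype == np.uint8
        assert inter["mask"].shape == img.shape
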