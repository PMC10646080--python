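"""Generator contracts: exact truth, determinism, growth/viability model."""

import dataclasses

import numpy as np
import pytest

from orgamorph.evaluation import pearson
from orgamorph.synthetic import (
    SimConfig,
    SimObject,
    generate_growth_series,
    generate_scene,
    generate_well_plate,
    rasterize_ellipse,
)


class TestRasterize:
    def test_circle_area_close_to_analytic(self):
        mask = rasterize_ellipse((128, 128), (50, 50), 0.0, (256, 256))
        assert mask.foreground_count() == pytest.approx(np.pi * 50**2, rel=0.01)

    def test_matches_bruteforce_pixel_test(self):
        cy, cx, a, b, th = 20.3, 24.7, 12.0, 7.0, 0.6
        mask = rasterize_ellipse((cy, cx), (a, b), th, (48, 48)).pixels
        cos, sin = np.cos(th), np.sin(th)
        for r in range(48):
            for c in range(48):
                u = (c - cx) * cos + (r - cy) * sin
                v = -(c - cx) * sin + (r - cy) * cos
                assert mask[r, c] == ((u / a) ** 2 + (v / b) ** 2 <= 1)

    def test_circle_eccentricity_zero(self):
        obj = SimObject((0, 0), 10, 10, 0.0)
        assert obj.eccentricity == 0.0

    def test_two_to_one_ellipse_eccentricity(self):
        obj = SimObject((0, 0), 20, 10, 0.0)
        assert obj.eccentricity == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            rasterize_ellipse((5, 5), (0.0, 1.0), 0.0, (10, 10))


class TestGenerateScene:
    def test_empty_config_gives_empty_mask(self):
        cfg = SimConfig(height=128, width=128, n_organoids=0, seed=1)
        _, mask, objects = generate_scene(cfg)
        assert mask.foreground_count() == 0
        assert objects == []

    def test_component_count_matches_n_organoids(self):
        from skimage import measure

        cfg = SimConfig(height=384, width=384, n_organoids=5, seed=3)
        _, mask, _ = generate_scene(cfg)
        assert measure.label(mask.pixels, connectivity=2).max() == 5

    def test_same_seed_bit_identical(self, small_scene):
        cfg, image, mask, _ = small_scene
        image2, mask2, _ = generate_scene(dataclasses.replace(cfg))
        np.testing.assert_array_equal(image.pixels, image2.pixels)
        np.testing.assert_array_equal(mask.pixels, mask2.pixels)

    def test_mask_is_union_of_organoid_rasterizations(self, small_scene):
        cfg, _, mask, objects = small_scene
        union = np.zeros(mask.shape, dtype=bool)
        for o in objects:
            if not o.is_distractor:
                union |= rasterize_ellipse(
                    o.center, (o.a, o.b), o.orientation, mask.shape
                ).pixels
        np.testing.assert_array_equal(mask.pixels, union)

    def test_distractors_excluded_from_mask(self, small_scene):
        cfg, _, mask, objects = small_scene
        assert sum(o.is_distractor for o in objects) == cfg.n_outfocus_distractors
        for o in objects:
            if o.is_distractor:
                blob = rasterize_ellipse(
                    o.center, (o.a, o.b), o.orientation, mask.shape
                ).pixels
                assert not (mask.pixels & blob).any()

    def test_analytic_areas_match_mask_count(self, small_scene):
        _, _, mask, objects = small_scene
        analytic = sum(o.area for o in objects if not o.is_distractor)
        assert mask.foreground_count() == pytest.approx(analytic, rel=0.02)

    def test_oversized_organoid_rejected(self):
        cfg = SimConfig(
            height=64,
            width=64,
            n_organoids=1,
            diameter_median_um=400,
            diameter_min_um=400,
            diameter_max_um=400,
            um_per_px=1.0,
            seed=0,
        )
        with pytest.raises(ValueError):
            generate_scene(cfg)


class TestGrowthSeries:
    def test_noiseless_doubling_doubles_viability(self):
        cfg = SimConfig(height=256, width=256, n_organoids=3, seed=7)
        series = generate_growth_series(cfg, days=4, daily_growth=2.0, noise=0.0, n_wells=2)
        for w in range(2):
            v = series.viability[w]
            for d in range(1, 4):
                assert v[d] / v[d - 1] == pytest.approx(2.0, rel=0.02)

    def test_noiseless_proportionality_r_equals_one(self):
        cfg = SimConfig(height=256, width=256, n_organoids=3, seed=8)
        series = generate_growth_series(cfg, days=5, daily_growth=1.8, noise=0.0)
        r, _ = pearson(series.total_true_area.ravel(), series.viability.ravel())
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_noisy_series_still_strongly_correlated(self):
        cfg = SimConfig(height=256, width=256, n_organoids=3, seed=9)
        series = generate_growth_series(
            cfg, days=5, daily_growth=2.0, noise=0.05, n_wells=3
        )
        r, _ = pearson(series.total_true_area.ravel(), series.viability.ravel())
        assert r >= 0.95

    def test_plateau_slows_area_growth(self):
        cfg = SimConfig(height=256, width=256, n_organoids=3, seed=10)
        series = generate_growth_series(
            cfg, days=5, daily_growth=2.0, noise=0.0, plateau_day=4, plateau_growth=1.03
        )
        areas = series.total_true_area[0]
        assert areas[3] / areas[2] == pytest.approx(2.0, rel=0.05)
        assert areas[4] / areas[3] == pytest.approx(1.03, rel=0.05)

    def test_need_two_days(self):
        with pytest.raises(ValueError):
            generate_growth_series(SimConfig(seed=1), days=1)


class TestWellPlate:
    def test_serial_dilution_counts_cycle(self):
        cfg = SimConfig(height=192, width=192, n_organoids=4, seed=11)
        plate = generate_well_plate(cfg, n_wells=10, noise=0.0, organoid_counts=[4, 2, 1])
        counts = [
            sum(not o.is_distractor for o in plate.scenes[w][2]) for w in plate.wells
        ]
        assert counts == [4, 2, 1, 4, 2, 1, 4, 2, 1, 4]

    def test_viability_proportional_when_noiseless(self):
        cfg = SimConfig(height=192, width=192, seed=12)
        plate = generate_well_plate(cfg, n_wells=6, noise=0.0, organoid_counts=[3, 1])
        ratio = plate.viability / plate.total_true_area
        np.testing.assert_allclose(ratio, ratio[0])
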