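"""Image-operator unit and property tests against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from plic import (
    adaptive_erode_mask,
    bright_detail_image,
    bright_detail_intensity,
    bright_detail_similarity,
    compute_features,
    max_contour_position,
    max_pixel,
    morphology_mask,
    staining_area,
)
from plic.imageops import estimate_background

from _oracles import (
    oracle_adaptive_erode,
    oracle_mcp,
    oracle_max_pixel,
    oracle_morphology_mask,
    oracle_pearson_fisher,
    oracle_tophat,
)
from conftest import random_blob_image, random_mask


def disk_mask(side, radius, center=None):
    c = (side - 1) / 2 if center is None else center
    yy, xx = np.mgrid[0:side, 0:side]
    return np.hypot(yy - c, xx - c) <= radius


class TestMorphologyMask:
    def test_all_zero_grid_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            m = morphology_mask(np.zeros((15, 15)))
        assert not m.any()

    def test_bright_annulus_is_hole_filled_to_a_disk(self):
        side = 21
        ring = disk_mask(side, 8) & ~disk_mask(side, 5)
        img = np.where(ring, 100.0, 0.0)
        m = morphology_mask(img, threshold=50.0)
        assert np.array_equal(m, disk_mask(side, 8))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        img = random_blob_image(rng)
        thr = float(np.median(img))
        assert np.array_equal(
            morphology_mask(img, threshold=thr), oracle_morphology_mask(img, thr)
        )


class TestAdaptiveErodeMask:
    def test_percent_100_returns_base_unchanged(self):
        base = disk_mask(31, 12)
        assert np.array_equal(adaptive_erode_mask(base, 100), base)

    def test_disk_radius_20_percent_78_area_bracket(self):
        base = disk_mask(45, 20)
        m = adaptive_erode_mask(base, 78)
        ratio = m.sum() / base.sum()
        assert ratio >= 0.78
        # one further erosion step must drop below the target
        from _oracles import oracle_erode_once

        assert oracle_erode_once(m).sum() < 0.78 * base.sum()

    def test_percent_0_gives_last_nonempty_core(self):
        base = disk_mask(21, 8)
        m = adaptive_erode_mask(base, 0)
        assert m.any()
        from _oracles import oracle_erode_once

        assert not oracle_erode_once(m).any()

    def test_empty_base_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            m = adaptive_erode_mask(np.zeros((9, 9), bool), 50)
        assert not m.any()

    @pytest.mark.parametrize("seed,percent", [(s, p) for s in range(5)
                                              for p in (0, 30, 78, 95)])
    def test_matches_iterative_erosion_oracle(self, seed, percent):
        rng = np.random.default_rng(seed)
        base = random_mask(rng)
        assert np.array_equal(
            adaptive_erode_mask(base, percent), oracle_adaptive_erode(base, percent)
        )

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 10**6))
    def test_mask_nesting_monotone_in_percent(self, p1, p2, seed):
        if p1 > p2:
            p1, p2 = p2, p1
        base = random_mask(np.random.default_rng(seed), side=21)
        if not base.any():
            return
        inner = adaptive_erode_mask(base, p1)
        outer = adaptive_erode_mask(base, p2)
        assert not (inner & ~outer).any()
        assert not (outer & ~base).any()


class TestBrightDetail:
    def test_constant_grid_has_no_bright_detail(self):
        assert np.allclose(bright_detail_image(np.full((15, 15), 7.0)), 0.0)

    def test_single_pixel_keeps_its_value(self):
        img = np.zeros((15, 15))
        img[7, 7] = 42.0
        th = bright_detail_image(img, radius=3)
        assert th[7, 7] == pytest.approx(42.0)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("radius", [1, 3])
    def test_matches_min_max_scan_oracle(self, seed, radius):
        rng = np.random.default_rng(seed)
        img = random_blob_image(rng)
        got = bright_detail_image(img, radius)
        want = oracle_tophat(img, radius)
        assert np.allclose(got, want, rtol=0, atol=1e-9)
        assert got.min() >= 0

    def test_bdi_additive_over_disjoint_puncta(self):
        side = 31
        mask = np.ones((side, side), bool)
        a = np.zeros((side, side))
        b = np.zeros((side, side))
        a[5, 5] = 100.0
        b[25, 25] = 80.0
        bdi_sum = bright_detail_intensity(a + b, mask)
        assert bdi_sum == pytest.approx(
            bright_detail_intensity(a, mask) + bright_detail_intensity(b, mask)
        )

    @given(st.integers(0, 10**6), st.floats(0.1, 50), st.floats(1, 1000))
    def test_bdi_constant_invariant_and_scale_linear(self, seed, const, scale):
        rng = np.random.default_rng(seed)
        img = random_blob_image(rng, side=21)
        mask = disk_mask(21, 8)
        base = bright_detail_intensity(img, mask)
        assert bright_detail_intensity(img + const, mask) == pytest.approx(
            base, rel=1e-9, abs=1e-6
        )
        assert bright_detail_intensity(img * scale, mask) == pytest.approx(
            base * scale, rel=1e-9, abs=1e-6
        )


class TestMaxPixel:
    def test_constant_grid_is_zero_after_background_subtraction(self):
        img = np.full((15, 15), 5.0)
        assert max_pixel(img, disk_mask(15, 5)) == 0.0

    def test_direct_subtraction_example(self):
        img = np.full((15, 15), 10.0)
        img[7, 7] = 250.0
        assert max_pixel(img, disk_mask(15, 5)) == pytest.approx(240.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_with_same_background(self, seed):
        rng = np.random.default_rng(seed)
        img = random_blob_image(rng, integer=True)
        mask = random_mask(rng)
        if not mask.any() or mask.all():
            return
        bg = estimate_background(img, mask)
        assert max_pixel(img, mask) == oracle_max_pixel(img, mask, bg)

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert max_pixel(np.ones((9, 9)), np.zeros((9, 9), bool)) == 0.0


class TestMaxContourPosition:
    def test_central_punctum_lands_in_innermost_ring(self):
        side = 31
        img = np.ones((side, side))
        img[15, 15] = 500.0
        assert max_contour_position(img, disk_mask(side, 12), 8) <= 1 / 8

    def test_perimeter_ring_lands_in_outermost_bin(self):
        side = 31
        mask = disk_mask(side, 12)
        ring = mask & ~disk_mask(side, 11)
        img = np.where(ring, 500.0, 1.0)
        assert max_contour_position(img, mask, 8) >= 1 - 1 / 8

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_distance_binning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = random_blob_image(rng)
        mask = random_mask(rng)
        if not mask.any():
            return
        assert max_contour_position(img, mask, 8) == pytest.approx(
            oracle_mcp(img, mask, 8)
        )

    @given(st.integers(0, 10**6), st.floats(0.01, 100), st.integers(1, 3))
    def test_invariant_to_scaling_and_rotation(self, seed, scale, k):
        rng = np.random.default_rng(seed)
        img = random_blob_image(rng, side=21)
        mask = random_mask(rng, side=21)
        if not mask.any():
            return
        base = max_contour_position(img, mask)
        assert max_contour_position(img * scale, mask) == base
        assert max_contour_position(np.rot90(img, k), np.rot90(mask, k)) == base


class TestBrightDetailSimilarity:
    def test_fixed_5x5_grids_match_formula_oracle(self):
        a = np.array([
            [0, 1, 2, 3, 4],
            [5, 0, 1, 2, 3],
            [0, 9, 0, 1, 0],
            [2, 0, 7, 0, 1],
            [0, 3, 0, 5, 0],
        ], float)
        b = np.array([
            [1, 0, 3, 0, 2],
            [0, 8, 0, 1, 0],
            [4, 0, 6, 0, 3],
            [0, 2, 0, 9, 0],
            [5, 0, 1, 0, 4],
        ], float)
        mask = np.ones((5, 5), bool)
        got = bright_detail_similarity(a, b, mask, radius=1)
        want = oracle_pearson_fisher(
            oracle_tophat(a, 1)[mask], oracle_tophat(b, 1)[mask]
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_identical_nonconstant_input_hits_clipped_maximum(self):
        rng = np.random.default_rng(0)
        img = random_blob_image(rng)
        mask = disk_mask(31, 12)
        z = bright_detail_similarity(img, img, mask)
        assert z == pytest.approx(np.arctanh(0.999), rel=1e-12)
        assert z == pytest.approx(3.8, abs=0.1)

    def test_independent_patterns_have_small_similarity(self):
        rng = np.random.default_rng(1)
        mask = disk_mask(31, 14)
        a = rng.uniform(0, 100, (31, 31))
        b = rng.uniform(0, 100, (31, 31))
        assert abs(bright_detail_similarity(a, b, mask)) < 0.5

    def test_zero_variance_flags_zero(self):
        mask = disk_mask(15, 6)
        with pytest.warns(UserWarning):
            assert bright_detail_similarity(
                np.full((15, 15), 3.0), np.ones((15, 15)), mask
            ) == 0.0

    def test_tiny_mask_is_missing_feature(self):
        mask = np.zeros((15, 15), bool)
        mask[7, 7] = True
        with pytest.warns(UserWarning):
            assert np.isnan(
                bright_detail_similarity(np.ones((15, 15)), np.ones((15, 15)), mask)
            )

    @given(st.integers(0, 10**6), st.floats(0.1, 10), st.floats(0, 50))
    def test_symmetric_and_affine_invariant(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        a = random_blob_image(rng, side=21)
        b = random_blob_image(rng, side=21)
        mask = disk_mask(21, 9)
        z = bright_detail_similarity(a, b, mask)
        assert bright_detail_similarity(b, a, mask) == pytest.approx(z, rel=1e-9)
        assert bright_detail_similarity(a * scale + shift, b, mask) == pytest.approx(
            z, rel=1e-6, abs=1e-9
        )


class TestStainingArea:
    def test_compact_punctum_has_small_area_diffuse_has_large(self):
        side = 31
        mask = disk_mask(side, 12)
        punctum = np.zeros((side, side))
        punctum[15, 15] = 200.0
        diffuse = np.where(mask, 100.0, 0.0).astype(float)
        diffuse[15, 15] = 110.0  # peak so fraction-of-max is defined
        assert staining_area(punctum, mask) <= 5
        assert staining_area(diffuse, mask) >= 0.9 * mask.sum()

    def test_signal_free_cell_has_zero_area(self):
        assert staining_area(np.zeros((15, 15)), disk_mask(15, 6)) == 0.0


class TestComputeFeatures:
    def test_negative_noise_free_cell_has_zero_pla_signal(self, small_params):
        import dataclasses

        from plic import CellClass, generate_cell

        params = dataclasses.replace(small_params, noise_sd=0.0)
        rng = np.random.default_rng(0)
        cell, _ = generate_cell(CellClass.NEGATIVE, params, rng)
        feats = compute_features(cell)
        assert feats["PLA_bdi"] == 0.0
        assert feats["PLA_max_pixel"] == 0.0

    def test_batch_equals_single_cell_computation(self, small_params):
        from plic import extract_features, generate_sample, nuclear_scenario_mix

        cells, _ = generate_sample(
            12, nuclear_scenario_mix(0.5), small_params, seed=5
        )
        batch = extract_features(cells)
        for i in (0, 5, 11):
            single = compute_features(cells[i])
            row = batch.iloc[i]
            for key, val in single.items():
                assert row[key] == pytest.approx(val, nan_ok=True), key

    def test_every_feature_matches_its_single_operator_oracle(self, small_params):
        from plic import generate_sample, nuclear_scenario_mix
        from plic.imageops import FeatureConfig

        cells, _ = generate_sample(
            6, nuclear_scenario_mix(0.5), small_params, seed=7
        )
        cfg = FeatureConfig()
        for cell in cells:
            feats = compute_features(cell, cfg)
            mask = morphology_mask(cell.channel("BF"))
            emask = adaptive_erode_mask(mask, 78.0)
            assert feats["mask_area"] == mask.sum()
            assert feats["erode_area"] == emask.sum()
            grid = cell.channel("PLA")
            assert feats["PLA_bdi"] == pytest.approx(
                bright_detail_intensity(grid, mask)
            )
            assert feats["PLA_max_pixel"] == pytest.approx(max_pixel(grid, mask))
            assert feats["PLA_mcp"] == pytest.approx(
                max_contour_position(grid, mask)
            )
            assert feats["PLA_area"] == pytest.approx(staining_area(grid, mask))
            assert feats["BDS_PLA_CD80"] == pytest.approx(
                bright_detail_similarity(grid, cell.channel("CD80"), mask)
            )
            assert feats["PLA_bdi_erode"] == pytest.approx(
                bright_detail_intensity(grid, emask)
            )
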