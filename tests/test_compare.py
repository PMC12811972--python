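"""Gamma index, dose-difference statistics, DVH, grid resampling."""

import numpy as np
import pytest

from brachyaudit import compare, tg43

from _oracles import brute_force_gamma, dvh_counting_oracle


def grid(values, origin=(0, 0, 0), spacing=(1, 1, 1)):
    return tg43.DoseGrid(np.array(origin, float), np.array(spacing, float),
                         np.asarray(values, float))


@pytest.fixture
def smooth_pair():
    """A smooth reference field and a noisy evaluated copy."""
    rng = np.random.default_rng(7)
    z, y, x = np.meshgrid(*[np.arange(9.0)] * 3, indexing="ij")
    ref = 2.0 + np.sin(x / 3) + 0.5 * np.cos(y / 2) + 0.2 * z / 8
    ev = ref * (1.0 + rng.normal(0, 0.02, ref.shape))
    return grid(ref), grid(ev)


class TestGammaMap:
    def test_identical_grids_give_zero_gamma(self, smooth_pair):
        ref, _ = smooth_pair
        crit = compare.GammaCriteria(3.0, 1.0, search_radius_mm=1.5)
        res = compare.gamma_map(ref, grid(ref.values.copy()), crit)
        assert np.nanmax(res.gamma) == 0.0
        assert res.pass_rate_pct == 100.0

    def test_uniform_offset_sits_exactly_on_boundary(self):
        ref = grid(np.full((7, 7, 7), 2.0))
        ev = grid(np.full((7, 7, 7), 2.0 * 1.03))
        crit = compare.GammaCriteria(3.0, 1.0, mode="local", search_radius_mm=1.5)
        res = compare.gamma_map(ref, ev, crit)
        assert np.allclose(res.gamma, 1.0, atol=1e-9)
        assert res.pass_rate_pct == 100.0  # gamma = 1 is a pass

    def test_matches_exhaustive_brute_force_exactly(self, smooth_pair):
        ref, ev = smooth_pair
        crit = compare.GammaCriteria(2.0, 2.0, mode="local", search_radius_mm=3.0,
                                     search_step_mm=0.2)
        res = compare.gamma_map(ref, ev, crit)
        oracle = brute_force_gamma(ref.voxel_centers(), ref.values.ravel(), ev, crit)
        assert np.abs(res.gamma.ravel() - oracle).max() == 0.0

    def test_relaxing_criteria_never_decreases_pass_rate(self, smooth_pair):
        ref, ev = smooth_pair
        ev = grid(ev.values * 1.03)
        rates = []
        for dd, dta in [(1.0, 0.5), (2.0, 0.5), (2.0, 1.0), (4.0, 1.0), (4.0, 2.0)]:
            crit = compare.GammaCriteria(dd, dta, search_radius_mm=2.0,
                                         search_step_mm=dta / 10)
            rates.append(compare.gamma_map(ref, ev, crit).pass_rate_pct)
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_global_gamma_below_local_where_ref_below_normalization(self, smooth_pair):
        ref, ev = smooth_pair
        norm = float(ref.values.max())
        local = compare.gamma_map(ref, ev, compare.GammaCriteria(2.0, 1.0, search_radius_mm=1.5))
        glob = compare.gamma_map(
            ref, ev, compare.GammaCriteria(2.0, 1.0, mode="global",
                                           normalization_dose_gy=norm, search_radius_mm=1.5)
        )
        below = ref.values < norm
        assert np.all(glob.gamma[below] <= local.gamma[below] + 1e-12)

    def test_sub_dta_translation_passes_everywhere(self):
        z, y, x = np.meshgrid(*[np.arange(11.0)] * 3, indexing="ij")
        vals = 5.0 + np.sin(x / 4) + np.cos(y / 5) + z / 20
        ref = grid(vals)
        ev = grid(vals, origin=(0.5, 0, 0))  # dta/2 shift of the eval frame
        crit = compare.GammaCriteria(3.0, 1.0, search_radius_mm=1.5)
        res = compare.gamma_map(ref, ev, crit)
        inner = res.gamma[2:-2, 2:-2, 2:-2]
        assert np.all(inner <= 1.0 + 1e-12)

    def test_cutoffs_restrict_evaluation(self):
        vals = np.linspace(0.5, 30.0, 5 * 5 * 5).reshape(5, 5, 5)
        ref = grid(vals)
        crit = compare.GammaCriteria(3.0, 1.0, low_cutoff_gy=1.5, high_cutoff_gy=24.0,
                                     search_radius_mm=1.5)
        res = compare.gamma_map(ref, grid(vals.copy()), crit)
        expected = int(((vals >= 1.5) & (vals <= 24.0)).sum())
        assert res.total == expected
        assert np.isnan(res.gamma[vals < 1.5]).all()

    def test_empty_comparison_raises(self):
        ref = grid(np.full((3, 3, 3), 0.5))
        crit = compare.GammaCriteria(3.0, 1.0, low_cutoff_gy=1.5, search_radius_mm=1.5)
        with pytest.raises(compare.EmptyComparisonError):
            compare.gamma_map(ref, grid(ref.values.copy()), crit)

    def test_step_must_respect_dta_tenth(self):
        with pytest.raises(ValueError, match="DTA/10"):
            compare.GammaCriteria(3.0, 1.0, search_step_mm=0.5)


class TestGammaPoints:
    def test_points_sampled_from_grid_all_pass_with_zero_gamma(self, smooth_pair):
        ref, _ = smooth_pair
        pts = ref.voxel_centers()[[10, 100, 300]]
        doses = ref.sample(pts)
        crit = compare.GammaCriteria(3.0, 1.0, search_radius_mm=1.5)
        res = compare.gamma_points(pts, doses, ref, crit)
        assert np.allclose(res.gamma[np.isfinite(res.gamma)], 0.0, atol=1e-12)
        assert res.summary.startswith("3 out of 3")

    def test_double_criterion_deviation_in_uniform_field_fails_at_two(self):
        ev = grid(np.full((9, 9, 9), 2.0))
        pts = np.array([[4.0, 4.0, 4.0]])
        meas = np.array([2.0 / 1.06])  # eval is +6% relative to the point, dd = 3%
        crit = compare.GammaCriteria(3.0, 1.0, mode="local", search_radius_mm=3.0)
        res = compare.gamma_points(pts, meas, ev, crit)
        assert res.gamma[0] == pytest.approx(2.0, rel=1e-9)
        assert res.pass_count == 0

    def test_agrees_with_brute_force_on_random_points(self, smooth_pair):
        ref, ev = smooth_pair
        rng = np.random.default_rng(5)
        pts = rng.uniform(1.5, 6.5, (10, 3))
        doses = ref.sample(pts) * (1 + rng.normal(0, 0.02, 10))
        crit = compare.GammaCriteria(2.0, 1.0, search_radius_mm=2.0)
        res = compare.gamma_points(pts, doses, ev, crit)
        oracle = brute_force_gamma(pts, doses, ev, crit)
        assert np.abs(res.gamma - oracle).max() == 0.0

    def test_point_outside_extent_excluded_with_warning(self, smooth_pair):
        ref, ev = smooth_pair
        pts = np.array([[4.0, 4.0, 4.0], [50.0, 50.0, 50.0]])
        crit = compare.GammaCriteria(3.0, 1.0, search_radius_mm=1.5)
        with pytest.warns(UserWarning, match="outside"):
            res = compare.gamma_points(pts, np.array([2.0, 2.0]), ev, crit)
        assert res.total == 1
        assert np.isnan(res.gamma[1])


class TestDiffMapAndHistogram:
    def test_identical_fields_give_zero_difference(self, smooth_pair):
        ref, _ = smooth_pair
        diff = compare.local_diff_map(ref, grid(ref.values.copy()))
        assert np.nanmax(np.abs(diff)) < 1e-9

    def test_five_percent_scale_gives_five_percent_everywhere(self, smooth_pair):
        ref, _ = smooth_pair
        diff = compare.local_diff_map(ref, grid(ref.values * 1.05))
        assert np.allclose(diff, 5.0, atol=1e-9)

    def test_spot_checks_against_direct_formula(self, smooth_pair):
        ref, ev = smooth_pair
        diff = compare.local_diff_map(ref, ev)
        rng = np.random.default_rng(0)
        flat_ref = ref.values.ravel()
        flat_ev = ev.sample(ref.voxel_centers())
        flat_diff = diff.ravel()
        for i in rng.integers(0, flat_ref.size, 100):
            expect = (flat_ev[i] - flat_ref[i]) / flat_ref[i] * 100.0
            assert flat_diff[i] == pytest.approx(expect, rel=1e-12)

    def test_constant_offset_occupies_single_bin(self):
        ref = grid(np.full((4, 4, 4), 3.0))
        stats = compare.diff_histogram(np.full((4, 4, 4), 2.0), ref)
        assert stats.median_pct == pytest.approx(2.0)
        assert (stats.frequencies > 0).sum() == 1

    def test_percentiles_match_sorting_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(2.0, 3.0, (8, 8, 8))
        ref = grid(np.full((8, 8, 8), 3.0))
        stats = compare.diff_histogram(vals, ref)
        s = np.sort(vals.ravel())
        assert stats.median_pct == pytest.approx(np.median(s), rel=1e-12)
        assert stats.percentile_range_pct[0] == pytest.approx(np.percentile(s, 2.5), rel=1e-9)
        assert stats.percentile_range_pct[1] == pytest.approx(np.percentile(s, 97.5), rel=1e-9)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        ref = grid(np.full((6, 6, 6), 3.0))
        stats = compare.diff_histogram(rng.normal(0, 2, (6, 6, 6)), ref)
        assert stats.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reference_dose_cutoffs_applied(self):
        ref_vals = np.array([0.5, 2.0, 30.0, 10.0]).reshape(1, 1, 4)
        diff = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        stats = compare.diff_histogram(diff, grid(ref_vals), 1.5, 24.0)
        assert stats.n == 2  # only the 2 Gy and 10 Gy voxels survive

    def test_empty_after_cutoffs_raises(self):
        ref = grid(np.full((2, 2, 2), 0.1))
        with pytest.raises(compare.EmptyComparisonError):
            compare.diff_histogram(np.ones((2, 2, 2)), ref)


class TestDVH:
    def test_uniform_structure_is_step_function(self):
        g = grid(np.full((4, 4, 4), 3.0))
        dvh = compare.compute_dvh(g, np.ones((4, 4, 4), bool), "uniform")
        assert dvh.d_mean_gy == pytest.approx(3.0)
        assert dvh.d_max_gy == pytest.approx(3.0)
        assert dvh.volume_pct[0] == 100.0
        assert dvh.volume_pct[dvh.dose_gy <= 3.0].min() == 100.0

    def test_curve_properties(self, smooth_pair):
        ref, _ = smooth_pair
        mask = np.zeros(ref.values.shape, bool)
        mask[2:7, 2:7, 2:7] = True
        dvh = compare.compute_dvh(ref, mask)
        assert dvh.volume_pct[0] == 100.0
        assert np.all(np.diff(dvh.volume_pct) <= 1e-12)
        assert dvh.volume_pct[-1] == 0.0

    def test_matches_counting_oracle_on_small_mask(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(1.0, 5.0, (5, 5, 5))
        g = grid(vals)
        dvh = compare.compute_dvh(g, np.ones((5, 5, 5), bool), bin_width_gy=0.05)
        oracle = dvh_counting_oracle(vals, dvh.dose_gy)
        assert np.abs(dvh.volume_pct - oracle).max() < 1e-9

    def test_d90_definition(self):
        vals = np.linspace(1.0, 2.0, 1000).reshape(10, 10, 10)
        dvh = compare.compute_dvh(grid(vals), np.ones((10, 10, 10), bool), bin_width_gy=0.001)
        # 90% of voxels receive at least the 10th-percentile dose
        assert dvh.d90_gy == pytest.approx(np.percentile(vals, 10), abs=0.005)

    def test_empty_mask_raises(self, smooth_pair):
        ref, _ = smooth_pair
        with pytest.raises(compare.EmptyComparisonError):
            compare.compute_dvh(ref, np.zeros(ref.values.shape, bool))


class TestDownsample:
    def test_factor_one_is_identity(self, smooth_pair):
        ref, _ = smooth_pair
        out = compare.downsample_inplane(ref, 1)
        assert np.array_equal(out.values, ref.values)

    def test_spacing_follows_ct_convention(self):
        g = grid(np.ones((4, 8, 8)), spacing=(0.27, 0.27, 0.6))
        out = compare.downsample_inplane(g, 2)
        assert np.allclose(out.spacing_mm, [0.54, 0.54, 0.6])
        assert out.values.shape == (4, 4, 4)

    def test_dose_volume_integral_conserved(self):
        rng = np.random.default_rng(2)
        g = grid(rng.uniform(0, 5, (4, 8, 8)), spacing=(0.5, 0.5, 1.0))
        out = compare.downsample_inplane(g, 2)
        v_in = g.values.sum() * np.prod(g.spacing_mm)
        v_out = out.values.sum() * np.prod(out.spacing_mm)
        assert v_out == pytest.approx(v_in, rel=1e-9)

    def test_remainder_cropped_with_warning(self):
        g = grid(np.ones((2, 5, 5)))
        with pytest.warns(UserWarning, match="crop"):
            out = compare.downsample_inplane(g, 2)
        assert out.values.shape == (2, 2, 2)

    def test_block_mean_values(self):
        vals = np.arange(16.0).reshape(1, 4, 4)
        out = compare.downsample_inplane(grid(vals), 2)
        assert out.values[0, 0, 0] == pytest.approx(np.mean([0, 1, 4, 5]))
        # origin moves to the centre of the first block
        assert np.allclose(out.origin_mm, [0.5, 0.5, 0.0])
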