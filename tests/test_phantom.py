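"""Digital phantom, plan builder, and synthetic-data generators."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from brachyaudit import film, phantom, tg43


class TestGeometry:
    def test_datasheet_dimensions(self, geom):
        assert geom.external_dims_mm == (95.0, 100.0, 60.0)
        assert geom.catheter_separation_mm == 40.0
        assert geom.slab_thickness_mm == 10.0

    def test_film_plane_distances(self, geom):
        offs = sorted(geom.film_plane_offsets_mm)
        assert [abs(o) for o in offs] == [10.0, 10.0]  # film-to-catheter-plane 10 mm
        assert offs[1] - offs[0] == 20.0  # film-to-film 20 mm

    def test_osld_distances_are_construction_inputs(self, geom):
        for s in geom.osld_sockets:
            d = min(abs(s.center_mm[0] - x) for x in geom.catheter_x_mm)
            assert d in (12.0, 20.0)
            assert s.center_mm[1] == 0.0  # on the catheter plane

    def test_osld_pattern_point_symmetric_about_centroid(self, geom):
        centers = np.array([s.center_mm for s in geom.osld_sockets])
        reflected = -centers
        for r in reflected:
            assert np.any(np.all(np.abs(centers - r) < 1e-12, axis=1))

    def test_osld_minimum_spacing(self, geom):
        centers = np.array([s.center_mm for s in geom.osld_sockets])
        assert pdist(centers).min() >= 14.0

    def test_contradictory_override_rejected(self):
        with pytest.raises(phantom.GeometryError, match="separation"):
            phantom.build_default_phantom(seed=0, catheter_x_mm=(-10.0, 20.0))

    def test_pin_triangles_well_conditioned(self, geom):
        for pins in geom.pin_positions.values():
            p = np.asarray(pins)
            area = 0.5 * abs(phantom._cross2(p[1] - p[0], p[2] - p[0]))
            assert area > 50.0

    def test_reproducible_for_fixed_seed(self):
        g1 = phantom.build_default_phantom(seed=7)
        g2 = phantom.build_default_phantom(seed=7)
        for off in g1.film_plane_offsets_mm:
            assert np.array_equal(g1.pin_positions[off], g2.pin_positions[off])


class TestBuildPlan:
    def test_default_plan_has_36_dwells_in_two_catheters(self, plan):
        assert len(plan.dwells) == 36
        assert sorted(plan.catheters) == [1, 2]
        assert all(len(d) == 18 for d in plan.catheters.values())

    def test_dwell_step_spacing(self, plan):
        for dwells in plan.catheters.values():
            centers = np.array([d.center_mm for d in dwells])
            gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
            assert np.allclose(gaps, 2.0, atol=1e-9)

    def test_prescription_contract(self, plan, geom):
        doses = tg43.dose_at_points(plan, plan.prescription_points_mm)
        assert doses.mean() == pytest.approx(3.0, rel=1e-9)  # mean-exact
        assert np.abs(doses - 3.0).max() / 3.0 < 0.15  # bounded modulation

    def test_dwell_times_in_clinical_modulation_band(self, plan):
        times = np.array([d.dwell_time_s for d in plan.dwells])
        assert np.all(times > 0)
        assert times.max() / times.min() <= 3.0 * 1.05  # renormalization slack

    def test_zero_prescription_gives_zero_times(self, geom, source):
        p = phantom.build_plan(geom, source, prescription_gy=0.0)
        assert all(d.dwell_time_s == 0.0 for d in p.dwells)

    def test_non_integral_treatment_length_rejected(self, geom, source):
        with pytest.raises(phantom.GeometryError):
            phantom.build_plan(geom, source, step_mm=2.0, treatment_length_mm=33.0)


class TestInjectShift:
    def test_zero_offset_is_identity(self, plan):
        shifted = phantom.inject_catheter_shift(plan, 0.0)
        for a, b in zip(plan.dwells, shifted.dwells):
            assert np.array_equal(a.center_mm, b.center_mm)

    def test_two_mm_shift_moves_every_dwell_along_catheter(self, plan):
        shifted = phantom.inject_catheter_shift(plan, 2.0, which="both")
        for a, b in zip(plan.dwells, shifted.dwells):
            assert np.allclose(b.center_mm - a.center_mm, 2.0 * a.axis_direction, atol=1e-12)

    def test_dwell_times_bitwise_unchanged(self, plan):
        shifted = phantom.inject_catheter_shift(plan, 2.0)
        assert [d.dwell_time_s for d in shifted.dwells] == [d.dwell_time_s for d in plan.dwells]

    def test_single_catheter_selection(self, plan):
        shifted = phantom.inject_catheter_shift(plan, 2.0, which=1)
        assert np.allclose(
            shifted.catheters[1][0].center_mm - plan.catheters[1][0].center_mm, [0, 0, 2.0]
        )
        assert np.array_equal(shifted.catheters[2][0].center_mm, plan.catheters[2][0].center_mm)


class TestSyntheticCT:
    def test_default_voxel_size(self, ct):
        assert np.allclose(ct.spacing_mm, [0.27, 0.27, 0.6])

    def test_zero_noise_chips_exceed_background(self, geom):
        spec = phantom.SyntheticCTSpec(noise_sd_hu=0.0)
        stack = phantom.synthesize_ct(geom, spec)
        assert stack.values.max() == 3000  # pins
        chip_mask = stack.values == 2000
        assert chip_mask.sum() > 0
        assert spec.hu_chip > spec.hu_rw3

    def test_hu_ordering_enforced(self):
        with pytest.raises(ValueError):
            phantom.SyntheticCTSpec(hu_chip=4000.0, hu_pin=3000.0)

    def test_bit_reproducible_for_fixed_seed(self, geom):
        a = phantom.synthesize_ct(geom, phantom.SyntheticCTSpec(seed=5))
        b = phantom.synthesize_ct(geom, phantom.SyntheticCTSpec(seed=5))
        assert np.array_equal(a.values, b.values)


class TestSimulateOSLD:
    def test_noiseless_identity_factors_invert_exactly(self, plan, geom):
        from brachyaudit.osld import CorrectionFactors

        factors = {s.chip_id: CorrectionFactors() for s in geom.osld_sockets}
        nd = 2.5e-3
        df = phantom.simulate_osld_readouts(plan, geom, factors, nd, noise_rel=0.0, seed=0)
        assert np.allclose(df["signal"] * nd, df["true_mean_dose_gy"], rtol=1e-12)

    def test_ten_distinct_chip_records(self, plan, geom):
        from brachyaudit.osld import CorrectionFactors

        factors = {s.chip_id: CorrectionFactors() for s in geom.osld_sockets}
        df = phantom.simulate_osld_readouts(plan, geom, factors, 2.5e-3, seed=0)
        assert len(df) == 10
        assert df["chip_id"].nunique() == 10

    def test_seeded_reproducibility(self, plan, geom):
        from brachyaudit.osld import CorrectionFactors

        factors = {s.chip_id: CorrectionFactors() for s in geom.osld_sockets}
        a = phantom.simulate_osld_readouts(plan, geom, factors, 2.5e-3, seed=3)
        b = phantom.simulate_osld_readouts(plan, geom, factors, 2.5e-3, seed=3)
        assert np.array_equal(a["signal"].values, b["signal"].values)


class TestSimulateFilm:
    def test_pixel_pitch_matches_150_dpi(self, plan, geom):
        scan, _ = phantom.simulate_film_scan(plan, geom, 10.0, seed=0)
        assert scan.pixel_spacing_mm == pytest.approx(0.17)

    def test_zero_dose_plan_gives_uniform_unexposed_values_plus_holes(self, geom, source):
        p = phantom.build_plan(geom, source, prescription_gy=0.0)
        curve = phantom.true_film_curve()
        scan, _ = phantom.simulate_film_scan(p, geom, 10.0, curve=curve, noise_rel=0.0,
                                             seed=0, hole_tear_sd_mm=0.0)
        px = scan.pixels.astype(float)
        holes = px.sum(axis=2) > 0.9 * px.sum(axis=2).max()
        for ch in range(3):
            vals = px[:, :, ch][~holes]
            assert np.allclose(vals, curve.unexposed_pv[ch], atol=1.0)
        assert holes.sum() > 0

    def test_round_trip_dose_recovery_above_cutoff(self, plan, geom):
        truth = phantom.true_film_curve()
        scan, placement = phantom.simulate_film_scan(
            plan, geom, 10.0, curve=truth, noise_rel=0.0, seed=0, hole_tear_sd_mm=0.0
        )
        dose_map, _, _ = film.film_to_dose(scan, truth)
        xs = np.arange(-35, 35.1, 2.5)
        zs = np.arange(-40, 40.1, 2.5)
        zz, xx = np.meshgrid(zs, xs, indexing="ij")
        pts = np.stack([xx.ravel(), np.full(xx.size, 10.0), zz.ravel()], axis=1)
        # keep away from the pin holes, which carry no film
        pins = np.asarray(geom.pin_positions[10.0])
        far = np.all(np.linalg.norm(pts[:, None, [0, 2]] - pins[None], axis=2) > 3.0, axis=1)
        vals, missing = film.resample_to_ct(dose_map, scan.pixel_spacing_mm, placement, pts)
        ref = tg43.dose_at_points(plan, pts)
        k = far & ~missing & (ref > 1.5)
        rel = np.abs(vals[k] - ref[k]) / ref[k]
        assert np.percentile(rel, 95) < 0.02

    def test_seeded_reproducibility(self, plan, geom):
        a, _ = phantom.simulate_film_scan(plan, geom, -10.0, seed=9)
        b, _ = phantom.simulate_film_scan(plan, geom, -10.0, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_unknown_plane_rejected(self, plan, geom):
        with pytest.raises(phantom.GeometryError):
            phantom.simulate_film_scan(plan, geom, 5.0, seed=0)


class TestReferenceDose:
    def test_noise_is_multiplicative_and_seeded(self, plan):
        a = phantom.simulate_reference_dose(plan, [25, -5, -5], [1, 1, 1], (8, 8, 8),
                                            noise_rel=0.01, seed=4)
        b = phantom.simulate_reference_dose(plan, [25, -5, -5], [1, 1, 1], (8, 8, 8),
                                            noise_rel=0.01, seed=4)
        clean = tg43.accumulate_dose(plan, [25, -5, -5], [1, 1, 1], (8, 8, 8))
        assert np.array_equal(a.values, b.values)
        rel = (a.values - clean.values) / clean.values
        assert 0.003 < rel.std() < 0.03

    def test_structure_masks_disjoint_and_nonempty(self, geom, plan):
        grid = tg43.accumulate_dose(plan, [-20, -8, -30], [2, 2, 2], (21, 9, 31))
        masks = phantom.structure_masks(geom, grid)
        assert set(masks) == {"high dose region", "low dose region 1", "low dose region 2"}
        total = np.zeros_like(grid.values, dtype=int)
        for m in masks.values():
            assert m.sum() > 0
            total += m
        assert total.max() <= 1
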