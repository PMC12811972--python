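"""Film pipeline: calibration, dose conversion, fiducials, registration."""

import numpy as np
import pytest

from brachyaudit import film, phantom

from _oracles import rigid_fit_2d_oracle


@pytest.fixture(scope="module")
def truth_curve():
    return phantom.true_film_curve()


@pytest.fixture(scope="module")
def fitted_curve(truth_curve):
    pv, doses = phantom.simulate_calibration_pieces(curve=truth_curve, noise_rel=0.003, seed=2)
    return film.fit_calibration(pv, doses)


class TestCalibration:
    def test_twelve_piece_zero_to_14gy_design(self):
        assert len(phantom.FILM_CALIBRATION_DOSES_GY) == 12
        assert min(phantom.FILM_CALIBRATION_DOSES_GY) == 0.0
        assert max(phantom.FILM_CALIBRATION_DOSES_GY) == 14.0

    def test_zero_dose_piece_maps_to_zero(self, fitted_curve):
        for ch in range(3):
            assert fitted_curve.dose_from_netod(0.0, ch) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_inversion_within_1pct_over_working_range(self, truth_curve, fitted_curve):
        doses = np.linspace(1.5, 14.0, 40)
        for ch in range(3):
            netod = truth_curve.netod_from_dose(doses, ch)
            rec = fitted_curve.dose_from_netod(netod, ch)
            assert np.max(np.abs(rec - doses) / doses) < 0.01

    def test_non_monotone_data_rejected(self):
        pv = np.tile([[40000.0], [30000.0], [35000.0], [20000.0]], (1, 3))
        with pytest.raises(film.CalibrationError, match="monotone"):
            film.fit_calibration(pv, np.array([0.0, 2.0, 4.0, 8.0]))

    def test_missing_unirradiated_piece_rejected(self):
        pv = np.tile([[40000.0], [30000.0], [25000.0], [20000.0]], (1, 3))
        with pytest.raises(film.CalibrationError, match="0 Gy"):
            film.fit_calibration(pv, np.array([1.0, 2.0, 4.0, 8.0]))


class TestFilmToDose:
    def test_uniform_exposure_recovers_uniform_dose(self, truth_curve):
        pv = np.zeros((40, 50, 3), dtype=np.uint16)
        for ch in range(3):
            netod = truth_curve.netod_from_dose(4.0, ch)
            pv[:, :, ch] = int(round(truth_curve.unexposed_pv[ch] * 10 ** (-netod)))
        scan = film.FilmScan(pv, 0.17)
        dose, mask, _ = film.film_to_dose(scan, truth_curve)
        assert np.allclose(dose, 4.0, rtol=0.01)
        assert not mask.any()

    def test_unexposed_region_flagged_below_cutoff(self, truth_curve):
        pv = np.zeros((10, 10, 3), dtype=np.uint16)
        for ch in range(3):
            pv[:, :, ch] = int(truth_curve.unexposed_pv[ch])
        dose, mask, _ = film.film_to_dose(film.FilmScan(pv, 0.17), truth_curve)
        assert mask.all()

    def test_out_of_range_pixels_clipped_and_counted(self, truth_curve):
        pv = np.full((5, 5, 3), 1000, dtype=np.uint16)  # nearly opaque -> huge dose
        dose, _, report = film.film_to_dose(film.FilmScan(pv, 0.17), truth_curve)
        assert report["n_clipped"] > 0
        assert dose.max() <= truth_curve.dose_range_gy[1] + 1e-9


class TestPinHoleDetection:
    def test_round_trip_and_count(self, plan, geom):
        scan, placement = phantom.simulate_film_scan(
            plan, geom, 10.0, seed=5, hole_tear_sd_mm=0.0
        )
        holes = film.detect_pin_holes(scan)
        pins_xz = np.asarray(geom.pin_positions[10.0])
        pins_ct = np.stack([pins_xz[:, 0], np.full(3, 10.0), pins_xz[:, 1]], axis=1)
        truth_uv = placement.ct_to_film(pins_ct)
        truth_uv = truth_uv[np.lexsort((truth_uv[:, 0], truth_uv[:, 1]))]
        assert holes.shape == (3, 2)
        assert np.abs(holes - truth_uv).max() < 0.2

    def test_invariant_to_global_intensity_scaling(self, plan, geom):
        scan, _ = phantom.simulate_film_scan(plan, geom, 10.0, seed=5, hole_tear_sd_mm=0.0)
        holes1 = film.detect_pin_holes(scan)
        dimmed = film.FilmScan((scan.pixels // 2).astype(np.uint16), scan.pixel_spacing_mm)
        holes2 = film.detect_pin_holes(dimmed)
        assert np.abs(holes1 - holes2).max() < 0.05

    def test_wrong_count_raises(self, plan, geom):
        scan, _ = phantom.simulate_film_scan(plan, geom, 10.0, seed=5)
        with pytest.raises(film.DetectionError):
            film.detect_pin_holes(scan, expected=4)


class TestPinCTDetection:
    def test_round_trip_and_plane_proximity(self, geom, ct):
        for off in geom.film_plane_offsets_mm:
            pins = film.detect_pins_ct(ct, off)
            truth = np.asarray(geom.pin_positions[off])
            truth3 = np.stack([truth[:, 0], np.full(3, float(off)), truth[:, 1]], axis=1)
            truth3 = truth3[np.lexsort((truth3[:, 0], truth3[:, 2]))]
            assert pins.shape == (3, 3)
            assert np.abs(pins - truth3).max() < 0.3
            assert np.abs(pins[:, 1] - off).max() <= 2.0


def random_transform(rng):
    ang = np.deg2rad(rng.uniform(-30, 30))
    r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = rng.uniform(-10, 10, 2)
    return film.RigidFilmTransform(r, t, 10.0, flip=bool(rng.integers(0, 2)))


def scalene_triangle(rng):
    while True:
        pts = rng.uniform(-40, 40, (3, 2))
        d = np.sort([np.linalg.norm(pts[i] - pts[j]) for i, j in ((0, 1), (1, 2), (2, 0))])
        area = 0.5 * abs(film._cross2(pts[1] - pts[0], pts[2] - pts[0]))
        if area > 200 and d[0] > 15 and np.min(np.diff(d)) > 3.0:
            return pts


class TestRegistration:
    def test_identity_correspondence(self):
        pts = np.array([[0.0, 0.0], [30.0, 5.0], [10.0, 40.0]])
        ct = np.stack([pts[:, 0], np.full(3, 10.0), pts[:, 1]], axis=1)
        tf, corr = film.solve_registration(pts, ct)
        assert tf.fre_mm == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(2), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)
        assert not tf.flip

    def test_known_rotation_translation_recovered(self):
        rng = np.random.default_rng(3)
        src = scalene_triangle(rng)
        ang = np.deg2rad(7.0)
        r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        dst2 = src @ r.T + np.array([3.2, -1.4])
        ct = np.stack([dst2[:, 0], np.full(3, -10.0), dst2[:, 1]], axis=1)
        tf, _ = film.solve_registration(src, ct)
        assert tf.angle_deg == pytest.approx(7.0, abs=1e-6)
        assert np.allclose(tf.translation, [3.2, -1.4], atol=1e-6)

    def test_recovers_200_random_transforms(self):
        """Rotations to 0.05 deg and translations to 0.05 mm, with and
        without the scan-face flip, from exact correspondences."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            src = scalene_triangle(rng)
            truth = random_transform(rng)
            ct = truth.film_to_ct(src)
            perm = rng.permutation(3)
            tf, _ = film.solve_registration(src, ct[perm])
            assert tf.flip == truth.flip
            assert abs(tf.angle_deg - truth.angle_deg) < 0.05
            assert np.abs(tf.translation - truth.translation).max() < 0.05
            # and the mapping agrees everywhere, not only at the fiducials
            probe = rng.uniform(-30, 30, (5, 2))
            assert np.abs(tf.film_to_ct(probe) - truth.film_to_ct(probe)).max() < 0.05

    def test_fre_matches_independent_least_squares_fit(self):
        rng = np.random.default_rng(21)
        src = scalene_triangle(rng)
        truth = random_transform(rng)
        ct = truth.film_to_ct(src)
        ct[:, [0, 2]] += rng.normal(0, 0.3, (3, 2))  # perturb fiducials
        tf, _ = film.solve_registration(src, ct, match_tolerance_mm=2.0)
        flipped = src.copy()
        if truth.flip:
            flipped[:, 0] = -flipped[:, 0]
        _, _, fre_oracle = rigid_fit_2d_oracle(flipped, ct[:, [0, 2]])
        assert tf.fre_mm == pytest.approx(fre_oracle, abs=1e-9)

    def test_equilateral_triangle_is_ambiguous(self):
        ang = np.deg2rad([90.0, 210.0, 330.0])
        pts = 30.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        ct = np.stack([pts[:, 0], np.full(3, 10.0), pts[:, 1]], axis=1)
        with pytest.raises(film.AmbiguousCorrespondenceError):
            film.solve_registration(pts, ct)

    def test_no_match_outside_tolerance(self):
        pts = np.array([[0.0, 0.0], [30.0, 5.0], [10.0, 40.0]])
        ct = np.stack([2 * pts[:, 0], np.full(3, 10.0), 2 * pts[:, 1]], axis=1)  # scaled
        with pytest.raises(film.DetectionError):
            film.solve_registration(pts, ct)


class TestResample:
    def test_identity_transform_preserves_values(self):
        dose = np.arange(30.0).reshape(5, 6)
        tf = film.RigidFilmTransform(np.eye(2), np.zeros(2), 0.0)
        # targets exactly at the pixel centres
        uu, vv = np.meshgrid(np.arange(6) * 1.0, np.arange(5) * 1.0)
        pts = np.stack([uu.ravel(), np.zeros(uu.size), vv.ravel()], axis=1)
        vals, missing = film.resample_to_ct(dose, 1.0, tf, pts)
        assert not missing.any()
        assert np.allclose(vals.reshape(5, 6), dose, atol=1e-12)

    def test_integer_pixel_translation_shifts_indices(self):
        dose = np.arange(30.0).reshape(5, 6)
        tf = film.RigidFilmTransform(np.eye(2), np.array([2.0, 1.0]), 0.0)  # film -> CT
        pts = np.array([[4.0, 0.0, 3.0]])  # maps back to film (2, 2) = row 2, col 2
        vals, _ = film.resample_to_ct(dose, 1.0, tf, pts)
        assert vals[0] == pytest.approx(dose[2, 2], abs=1e-12)

    def test_outside_extent_flagged_missing(self):
        dose = np.ones((5, 6))
        tf = film.RigidFilmTransform(np.eye(2), np.zeros(2), 0.0)
        vals, missing = film.resample_to_ct(dose, 1.0, tf, np.array([[50.0, 0.0, 0.0]]))
        assert missing.all()
        assert np.isnan(vals).all()
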