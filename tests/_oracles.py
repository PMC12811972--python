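"""Independent reference implementations used only to check the package.

Each oracle is deliberately coded from first principles (quadrature,
exhaustive search, closed forms) and stays independent of the code paths it
verifies.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator, interp1d


def quadrature_geometry_factor(r_cm, theta_deg, length_cm, n=10_000):
    """Line-source geometry function by midpoint quadrature of the
    1/rho^2 line integral over n source segments."""
    th = np.deg2rad(theta_deg)
    px, pz = r_cm * np.sin(th), r_cm * np.cos(th)
    l = (np.arange(n) + 0.5) / n * length_cm - length_cm / 2.0
    rho2 = px**2 + (pz - l) ** 2
    return float(np.mean(1.0 / rho2))


def tg43_product_oracle(source, r_cm, theta_deg, n=20_000):
    """Independent evaluation of the TG43 product formula with separately
    coded interpolators (scipy) and a quadrature geometry function."""
    g = interp1d(source.g_radii_cm, source.g_values)(r_cm)
    th = 180.0 - theta_deg if theta_deg > 90.0 else theta_deg
    f = RegularGridInterpolator(
        (source.f_radii_cm, source.f_angles_deg), source.f_values
    )([[np.clip(r_cm, source.f_radii_cm[0], source.f_radii_cm[-1]), th]])[0]
    gl = quadrature_geometry_factor(r_cm, theta_deg, source.active_length_cm, n)
    gl_ref = quadrature_geometry_factor(1.0, 90.0, source.active_length_cm, n)
    return source.air_kerma_strength * source.dose_rate_constant * gl / gl_ref * g * f


def brute_force_gamma(ref_points, ref_doses, eval_grid, crit):
    """Exhaustive gamma over the full search lattice, no pruning."""
    from brachyaudit.compare import _search_offsets

    offsets, dists = _search_offsets(crit)
    dist_term = (dists / crit.dta_mm) ** 2
    out = np.empty(len(ref_points))
    for i, (p, d) in enumerate(zip(np.atleast_2d(ref_points), np.atleast_1d(ref_doses))):
        vals = eval_grid.sample(p[None, :] + offsets)
        norm = (
            d * crit.dose_diff_pct / 100.0
            if crit.mode == "local"
            else crit.normalization_dose_gy * crit.dose_diff_pct / 100.0
        )
        g2 = ((vals - d) / norm) ** 2 + dist_term
        out[i] = np.sqrt(np.min(np.where(np.isnan(g2), np.inf, g2)))
    return out


def rigid_fit_2d_oracle(src, dst):
    """Closed-form 2D rigid fit via the analytic optimal-angle formula
    (independent of the SVD route): theta* = atan2(sum cross, sum dot)."""
    sc = src - src.mean(axis=0)
    dc = dst - dst.mean(axis=0)
    num = float(np.sum(sc[:, 0] * dc[:, 1] - sc[:, 1] * dc[:, 0]))
    den = float(np.sum(sc[:, 0] * dc[:, 0] + sc[:, 1] * dc[:, 1]))
    ang = np.arctan2(num, den)
    r = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = dst.mean(axis=0) - r @ src.mean(axis=0)
    res = src @ r.T + t - dst
    fre = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return r, t, fre


def dvh_counting_oracle(doses, axis):
    """Cumulative DVH by explicit voxel counting."""
    doses = np.asarray(doses, dtype=float).ravel()
    return np.array([100.0 * np.sum(doses >= d) / doses.size for d in axis])
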