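"""Orchestration of the three-branch remote dosimetry audit.

An audit run compares, for one treatment plan on the audit phantom:

* the OSLD branch — ten point-approximating chip measurements against the
  TPS dose grid with a gamma test at criteria derived from the OSL
  uncertainty budget (5%/1 mm);
* the film branch — two registered 2D film dose maps against the TPS grid
  at the film-budget criteria (4%/2 mm, 1.5 Gy low cutoff);
* the computational branch — the TPS grid against an independently computed
  reference 3D dose (here a simulated stochastic reference), via local
  dose-difference maps/histograms and DVH comparison.

A deliberate catheter-tip reconstruction error shifts the *delivered* dose
relative to where the planning system believes the catheters are: the two
experimental branches see it, the computational branch (which only ever
looks at the exported plan) does not.

Every random draw flows from one run-level seed; reports embed the seed,
criteria, cutoffs and versions needed to re-execute the run exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import compare, film as film_mod, osld as osld_mod, phantom, tg43, uncertainty

__all__ = ["AuditConfig", "AuditRun", "ReportDocument", "run_audit"]


@dataclass
class AuditConfig:
    """Configuration snapshot of an audit run; immutable once the run starts."""

    seed: int = 1
    catheter_shift_mm: float = 0.0
    prescription_gy: float = 3.0
    tps_grid_spacing_mm: float = 1.0
    film_compare_spacing_mm: float = 1.0
    osld_noise_rel: float = 0.01
    standard_noise_rel: float = 0.015
    film_noise_rel: float = 0.01
    reference_noise_rel: float = 0.01
    # systematic-error model of the measurement chain; magnitudes follow the
    # uncertainty budget (draws truncated at 2 sigma; the shared beam-quality
    # error at 1.5 sigma, since part of its budget entry is the side study's
    # type-A spread, not a bias)
    delivery_scale_sd: float = 0.015  # Sk + delivery chain, shared
    catheter_recon_sd_mm: float = 0.6  # one CT slice, per catheter, along z
    kl_error_sd: float = 0.017  # batch linearity, shared
    kq_error_sd: float = 0.020  # beam quality, shared
    ks_i_sd: float = 0.007  # per chip
    ktheta_sd: float = 0.014  # per chip
    film_cal_sys_sd: float = 0.02  # film calibration chain, shared per run
    # fiducial-matching tolerance; generous enough for torn pin holes
    registration_match_tolerance_mm: float = 2.5
    kq: float = osld_mod.DEFAULT_KQ
    kq_unc_pct: float = osld_mod.DEFAULT_KQ_UNCERTAINTY_PCT
    use_ct_localization: bool = True
    ct_noise_sd_hu: float = 20.0
    high_cutoff_factor: float = 8.0  # TPS near-source threshold, x prescription
    low_cutoff_gy: float = film_mod.LOW_DOSE_CUTOFF_GY
    # branch verdict action levels
    osld_min_global_pass_fraction: float = 1.0
    film_min_pass_pct: float = 90.0
    comp_max_median_abs_pct: float = 5.0

    def frozen(self) -> dict:
        return asdict(self)


@dataclass
class ReportDocument:
    """Structured, losslessly serializable audit report."""

    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(_to_plain(self.data), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ReportDocument":
        return cls(json.loads(Path(path).read_text()))


@dataclass
class AuditRun:
    """All artefacts of one audit execution."""

    config: dict
    plan: tg43.Plan
    delivered_plan: tg43.Plan
    tps_grid: tg43.DoseGrid
    reference_grid: tg43.DoseGrid | None
    report: ReportDocument


def _to_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float):
        return round(obj, 10)  # keep reports byte-stable across platforms
    return obj


def _phantom_grid_spec(geom: phantom.PhantomGeometry, spacing: float):
    ext_x, ext_z, ext_y = geom.external_dims_mm
    nx = int(round(ext_x / spacing))
    ny = int(round(ext_y / spacing))
    nz = int(round(ext_z / spacing))
    origin = np.array([
        -(nx - 1) / 2.0 * spacing, -(ny - 1) / 2.0 * spacing, -(nz - 1) / 2.0 * spacing,
    ])
    return origin, np.array([spacing] * 3), (nx, ny, nz)


def run_audit(config: AuditConfig | None = None) -> AuditRun:
    """Execute the full three-branch audit on synthetic data.

    Stage failures are recorded in the report and dependent stages skipped;
    the report is emitted regardless.
    """
    cfg = config or AuditConfig()
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["ct", "standards", "osld", "film_a", "film_b", "film_cal",
             "reference", "systematics"],
            np.random.SeedSequence(cfg.seed).spawn(8),
        )
    }
    sub_seed = lambda name: int(streams[name].integers(0, 2**31 - 1))

    def tnorm(sd: float, trunc_sigma: float = 2.0) -> float:
        """Truncated-normal systematic draw (gross errors are caught by QA)."""
        if sd == 0:
            return 0.0
        rng = streams["systematics"]
        for _ in range(100):
            x = rng.normal(0.0, sd)
            if abs(x) <= trunc_sigma * sd:
                return float(x)
        return 0.0

    report: dict = {
        "config": cfg.frozen(),
        "seed": cfg.seed,
        "versions": {"brachyaudit": _pkg_version()},
        "stages": {},
        "verdicts": {},
    }

    geom = phantom.build_default_phantom(seed=cfg.seed)
    source = tg43.load_default_source()
    plan = phantom.build_plan(geom, source, prescription_gy=cfg.prescription_gy)

    # the physically delivered field differs from the TPS's picture of it:
    # a shared delivery-chain dose scale, a per-catheter reconstruction
    # offset along the catheter (one CT slice of uncertainty), and any
    # deliberately injected catheter-tip misidentification
    delivery_scale = 1.0 + tnorm(cfg.delivery_scale_sd)
    recon_offsets = {cid: tnorm(cfg.catheter_recon_sd_mm) for cid in sorted(plan.catheters)}
    delivered = plan
    for cid, off in recon_offsets.items():
        total = off + cfg.catheter_shift_mm
        if total:
            delivered = phantom.inject_catheter_shift(delivered, total, which=cid)
    if delivery_scale != 1.0:
        import dataclasses
        delivered = tg43.Plan(
            delivered.catheters,
            dataclasses.replace(
                source, air_kerma_strength=source.air_kerma_strength * delivery_scale
            ),
            delivered.prescription_dose_gy,
            delivered.prescription_points_mm,
            delivered.step_mm,
        )
    film_cal_error = tnorm(cfg.film_cal_sys_sd)
    osld_truth_shared = {
        "kL": 1.0 + tnorm(cfg.kl_error_sd),
        "kQ": cfg.kq * (1.0 + tnorm(cfg.kq_error_sd, trunc_sigma=1.5)),
    }
    report["plan"] = {
        "n_dwells": len(plan.dwells),
        "total_time_s": plan.total_time_s,
        "trak_u_h": tg43.trak(plan),
        "prescription_gy": cfg.prescription_gy,
        "catheter_shift_mm": cfg.catheter_shift_mm,
    }

    origin, spacing, dims = _phantom_grid_spec(geom, cfg.tps_grid_spacing_mm)
    tps_grid = tg43.accumulate_dose(plan, origin, spacing, dims)

    # budgets fix the gamma criteria; not tunable per run
    osl_budget = uncertainty.load_budget("osl")
    film_budget = uncertainty.load_budget("film")
    osl_dd, osl_dta = uncertainty.derive_criteria(osl_budget)
    film_dd, film_dta = uncertainty.derive_criteria(film_budget)
    high_cutoff = cfg.high_cutoff_factor * cfg.prescription_gy
    report["criteria"] = {
        "osld": {"dose_diff_pct": osl_dd, "dta_mm": osl_dta},
        "film": {"dose_diff_pct": film_dd, "dta_mm": film_dta},
        "low_cutoff_gy": cfg.low_cutoff_gy,
        "high_cutoff_gy": high_cutoff,
        "global_normalization_gy": cfg.prescription_gy,
        "budgets": {
            "osl": osl_budget.combine(),
            "film": film_budget.combine(),
        },
    }

    ct = None
    if cfg.use_ct_localization:
        spec = phantom.SyntheticCTSpec(noise_sd_hu=cfg.ct_noise_sd_hu, seed=sub_seed("ct"))
        ct = phantom.synthesize_ct(geom, spec)

    # ---------------- OSLD branch ----------------
    try:
        report["stages"]["osld"] = _osld_branch(
            cfg, geom, plan, delivered, tps_grid, ct, streams, sub_seed,
            osl_dd, osl_dta, osld_truth_shared,
        )
        osld_ok = True
    except Exception as exc:  # recorded, not fatal
        report["stages"]["osld"] = {"error": f"{type(exc).__name__}: {exc}"}
        osld_ok = False

    # ---------------- film branch ----------------
    try:
        report["stages"]["film"] = _film_branch(
            cfg, geom, delivered, tps_grid, ct, sub_seed, film_dd, film_dta,
            1.0 + film_cal_error,
        )
        film_ok = True
    except Exception as exc:
        report["stages"]["film"] = {"error": f"{type(exc).__name__}: {exc}"}
        film_ok = False

    # ---------------- computational branch ----------------
    reference = None
    try:
        reference = phantom.simulate_reference_dose(
            plan, origin, spacing, dims,
            noise_rel=cfg.reference_noise_rel, seed=sub_seed("reference"),
        )
        report["stages"]["computational"] = _computational_branch(
            cfg, geom, tps_grid, reference, high_cutoff,
        )
        comp_ok = True
    except Exception as exc:
        report["stages"]["computational"] = {"error": f"{type(exc).__name__}: {exc}"}
        comp_ok = False

    # ---------------- verdicts ----------------
    v = report["verdicts"]
    if osld_ok:
        st = report["stages"]["osld"]
        frac = st["gamma_global"]["pass_count"] / st["gamma_global"]["total"]
        v["osld"] = {
            "pass": frac >= cfg.osld_min_global_pass_fraction,
            "criterion": f"global gamma pass fraction >= {cfg.osld_min_global_pass_fraction}",
        }
    else:
        v["osld"] = {"pass": False, "criterion": "stage failed"}
    if film_ok:
        st = report["stages"]["film"]
        rates = [p["gamma_local"]["pass_rate_pct"] for p in st["planes"].values()]
        rates += [p["gamma_global"]["pass_rate_pct"] for p in st["planes"].values()]
        v["film"] = {
            "pass": min(rates) >= cfg.film_min_pass_pct,
            "criterion": f"all gamma pass rates >= {cfg.film_min_pass_pct}%",
        }
    else:
        v["film"] = {"pass": False, "criterion": "stage failed"}
    if comp_ok:
        st = report["stages"]["computational"]
        v["computational"] = {
            "pass": abs(st["diff_stats"]["median_pct"]) <= cfg.comp_max_median_abs_pct,
            "criterion": f"|median local dose difference| <= {cfg.comp_max_median_abs_pct}%",
        }
    else:
        v["computational"] = {"pass": False, "criterion": "stage failed"}
    report["overall_pass"] = all(x["pass"] for x in v.values())

    return AuditRun(cfg.frozen(), plan, delivered, tps_grid, reference, ReportDocument(report))


def _pkg_version() -> str:
    try:
        from importlib.metadata import version
        return version("brachyaudit")
    except Exception:
        return "unknown"


def _osld_branch(cfg, geom, plan, delivered, tps_grid, ct, streams, sub_seed, dd, dta,
                 truth_shared):
    # session calibration from nine simulated standards at 0.5 Gy
    nd_true = 2.5e-3
    rng = streams["standards"]
    standards = [
        osld_mod.OSLDReadout(f"std{i}", (0.5 / nd_true) * (1.0 + rng.normal(0.0, cfg.standard_noise_rel)))
        for i in range(9)
    ]
    session = osld_mod.session_calibration(
        osld_mod.CalibrationSession(standards, reference_dose_gy=0.5)
    )

    sys_rng = streams["systematics"]
    truth = {
        s.chip_id: osld_mod.CorrectionFactors(
            ks_i=1.0 + np.clip(sys_rng.normal(0.0, cfg.ks_i_sd), -2 * cfg.ks_i_sd, 2 * cfg.ks_i_sd),
            ktheta=1.0 + np.clip(sys_rng.normal(0.0, cfg.ktheta_sd), -2 * cfg.ktheta_sd, 2 * cfg.ktheta_sd),
            kL=truth_shared["kL"],
            kQ=truth_shared["kQ"],
        )
        for s in geom.osld_sockets
    }
    readouts = phantom.simulate_osld_readouts(
        delivered, geom, truth, nd_gy_per_count=nd_true,
        noise_rel=cfg.osld_noise_rel, seed=sub_seed("osld"),
    )

    if ct is not None:
        centroids = osld_mod.locate_active_volumes(ct)
    else:
        cents = np.array([s.center_mm for s in geom.osld_sockets])
        order = np.lexsort((np.round(cents[:, 2], 1), np.round(cents[:, 0], 1)))
        centroids = cents[order]

    rows = []
    doses = []
    for (_, r), center in zip(readouts.iterrows(), centroids):
        kvol = osld_mod.compute_kvol(plan, center)
        factors = osld_mod.CorrectionFactors(
            kQ=cfg.kq, kQ_unc_pct=cfg.kq_unc_pct,
            ktheta_unc_pct=1.4, kL_unc_pct=1.7, ks_i_unc_pct=0.7,
            kvol=kvol, kvol_unc_pct=0.8,
        )
        dw, unc = osld_mod.dose_from_readout(
            osld_mod.OSLDReadout(r["chip_id"], r["signal"]),
            session.nd_gy_per_count, factors,
            nd_unc_pct=session.type_a_unc_pct, extra_unc_pct=(1.5, 1.5, 0.8),
        )
        tps_dose = float(tps_grid.sample(center[None, :])[0])
        rows.append({
            "chip_id": r["chip_id"], "kvol": kvol,
            "measured_gy": dw, "uncertainty_pct": unc,
            "tps_gy": tps_dose,
            "local_diff_pct": 100.0 * (tps_dose - dw) / dw,
        })
        doses.append(dw)
    doses = np.array(doses)

    crit_local = compare.GammaCriteria(dd, dta, mode="local")
    crit_global = compare.GammaCriteria(
        dd, dta, mode="global", normalization_dose_gy=cfg.prescription_gy
    )
    g_local = compare.gamma_points(centroids, doses, tps_grid, crit_local)
    g_global = compare.gamma_points(centroids, doses, tps_grid, crit_global)
    diffs = np.array([r["local_diff_pct"] for r in rows])
    return {
        "nd_gy_per_count": session.nd_gy_per_count,
        "nd_type_a_unc_pct": session.type_a_unc_pct,
        "chips": rows,
        "kvol_range": [float(min(r["kvol"] for r in rows)), float(max(r["kvol"] for r in rows))],
        "gamma_local": {
            "pass_count": g_local.pass_count, "total": g_local.total,
            "pass_rate_pct": g_local.pass_rate_pct, "summary": g_local.summary,
        },
        "gamma_global": {
            "pass_count": g_global.pass_count, "total": g_global.total,
            "pass_rate_pct": g_global.pass_rate_pct, "summary": g_global.summary,
        },
        "local_diff_stats_pct": {
            "mean": float(diffs.mean()), "std": float(diffs.std(ddof=1)),
            "median": float(np.median(diffs)), "max_abs": float(np.abs(diffs).max()),
        },
    }


def _film_branch(cfg, geom, delivered, tps_grid, ct, sub_seed, dd, dta, cal_scale):
    pv, doses = phantom.simulate_calibration_pieces(seed=sub_seed("film_cal"))
    curve = film_mod.fit_calibration(pv, doses)
    out = {"calibration_rms_gy": float(np.sqrt(np.mean(curve.fit_residuals_gy**2))),
           "planes": {}}
    for stream, off in zip(("film_a", "film_b"), geom.film_plane_offsets_mm):
        scan, _truth = phantom.simulate_film_scan(
            delivered, geom, off, noise_rel=cfg.film_noise_rel, seed=sub_seed(stream),
            dose_scale=cal_scale,
        )
        dose_map, low_mask, conv_report = film_mod.film_to_dose(scan, curve)
        holes = film_mod.detect_pin_holes(scan)
        if ct is not None:
            pins = film_mod.detect_pins_ct(ct, off)
        else:
            pxz = np.asarray(geom.pin_positions[off])
            pins = np.stack([pxz[:, 0], np.full(3, float(off)), pxz[:, 1]], axis=1)
        transform, corr = film_mod.solve_registration(
            holes, pins, match_tolerance_mm=cfg.registration_match_tolerance_mm
        )

        # comparison lattice on the film plane, CT frame
        s = cfg.film_compare_spacing_mm
        half_x, half_z = geom.film_size_mm[0] / 2.0 - 2.0, geom.film_size_mm[1] / 2.0 - 2.0
        xs = np.arange(-half_x, half_x + 1e-9, s)
        zs = np.arange(-half_z, half_z + 1e-9, s)
        zz, xx = np.meshgrid(zs, xs, indexing="ij")
        pts = np.stack([xx.ravel(), np.full(xx.size, float(off)), zz.ravel()], axis=1)
        vals, missing = film_mod.resample_to_ct(dose_map, scan.pixel_spacing_mm, transform, pts)
        keep = ~missing & np.isfinite(vals) & (vals >= cfg.low_cutoff_gy)
        if not np.any(keep):
            raise compare.EmptyComparisonError("no film points above the low-dose cutoff")
        crit_local = compare.GammaCriteria(dd, dta, mode="local")
        crit_global = compare.GammaCriteria(
            dd, dta, mode="global", normalization_dose_gy=cfg.prescription_gy
        )
        g_local = compare.gamma_points(pts[keep], vals[keep], tps_grid, crit_local)
        g_global = compare.gamma_points(pts[keep], vals[keep], tps_grid, crit_global)
        out["planes"][f"{off:+.0f}mm"] = {
            "registration_fre_mm": transform.fre_mm,
            "registration_angle_deg": transform.angle_deg,
            "flip": bool(transform.flip),
            "n_compared": int(keep.sum()),
            "n_clipped_pixels": conv_report["n_clipped"],
            "gamma_local": {
                "pass_count": g_local.pass_count, "total": g_local.total,
                "pass_rate_pct": g_local.pass_rate_pct, "summary": g_local.summary,
            },
            "gamma_global": {
                "pass_count": g_global.pass_count, "total": g_global.total,
                "pass_rate_pct": g_global.pass_rate_pct, "summary": g_global.summary,
            },
        }
    return out


def _computational_branch(cfg, geom, tps_grid, reference, high_cutoff):
    diff = compare.local_diff_map(reference, tps_grid)
    stats = compare.diff_histogram(
        diff, reference, low_cutoff_gy=cfg.low_cutoff_gy, high_cutoff_gy=high_cutoff
    )
    masks = phantom.structure_masks(geom, reference)
    dvhs = {}
    for name, mask in masks.items():
        ref_dvh = compare.compute_dvh(reference, mask, name)
        tps_mask = phantom.structure_masks(geom, tps_grid)[name]
        tps_dvh = compare.compute_dvh(tps_grid, tps_mask, name)
        dvhs[name] = {
            "reference": {"d_mean_gy": ref_dvh.d_mean_gy, "d90_gy": ref_dvh.d90_gy,
                          "d_max_gy": ref_dvh.d_max_gy, "voxels": ref_dvh.voxel_count},
            "tps": {"d_mean_gy": tps_dvh.d_mean_gy, "d90_gy": tps_dvh.d90_gy,
                    "d_max_gy": tps_dvh.d_max_gy, "voxels": tps_dvh.voxel_count},
            "d_mean_diff_pct": 100.0 * (tps_dvh.d_mean_gy - ref_dvh.d_mean_gy) / ref_dvh.d_mean_gy,
        }
    return {
        "diff_stats": {
            "median_pct": stats.median_pct,
            "percentile_range_pct": list(stats.percentile_range_pct),
            "n_voxels": stats.n,
        },
        "histogram": {
            "bin_edges_pct": stats.bin_edges_pct.tolist(),
            "frequencies": stats.frequencies.tolist(),
        },
        "dvh": dvhs,
    }
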