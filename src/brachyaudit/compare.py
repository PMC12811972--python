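"""Dose-comparison machinery: 3D gamma index, local dose differences, DVHs.

The gamma index combines a dose-difference criterion (percent) and a
distance-to-agreement (DTA, mm):

    gamma(p_ref) = min over eval positions q of
        sqrt( (D_eval(q) - D_ref(p_ref))^2 / dd_norm^2 + |q - p_ref|^2 / dta^2 )

where ``dd_norm`` is the local reference dose times dd% ("local" mode) or a
fixed normalization dose times dd% ("global" mode).  gamma <= 1 is a pass.
The evaluated distribution is trilinearly interpolated on a fine isotropic
search lattice (step <= DTA/10); the search is exhaustive over the lattice
within the search radius, with a distance-sorted early exit that provably
returns the exhaustive minimum (an offset is only skipped once its distance
term alone exceeds the current best gamma).

Measurements serve as the reference dataset; the TPS grids are evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tg43 import DoseGrid

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "DiffStats",
    "DVH",
    "EmptyComparisonError",
    "gamma_map",
    "gamma_points",
    "local_diff_map",
    "diff_histogram",
    "compute_dvh",
    "downsample_inplane",
]


class EmptyComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma passing criteria and search controls."""

    dose_diff_pct: float
    dta_mm: float
    mode: str = "local"  # "local" | "global"
    normalization_dose_gy: float | None = None  # required in global mode
    low_cutoff_gy: float | None = None
    high_cutoff_gy: float | None = None
    search_step_mm: float | None = None  # default dta/10
    search_radius_mm: float | None = None  # default 3*dta

    def __post_init__(self) -> None:
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("criteria must be positive")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")
        if self.mode == "global" and not self.normalization_dose_gy:
            raise ValueError("global mode requires a normalization dose")
        if self.step_mm > self.dta_mm / 10.0 + 1e-12:
            raise ValueError("search step must not exceed DTA/10")

    @property
    def step_mm(self) -> float:
        return self.search_step_mm if self.search_step_mm else self.dta_mm / 10.0

    @property
    def radius_mm(self) -> float:
        return self.search_radius_mm if self.search_radius_mm else 3.0 * self.dta_mm


@dataclass
class GammaResult:
    """Per-point gamma values and the derived pass rate."""

    gamma: np.ndarray
    pass_count: int
    total: int

    @property
    def pass_rate_pct(self) -> float:
        return 100.0 * self.pass_count / self.total if self.total else float("nan")

    @property
    def summary(self) -> str:
        return f"{self.pass_count} out of {self.total} ({self.pass_rate_pct:.1f}%)"


@dataclass
class DiffStats:
    """Local dose-difference histogram (1%-wide bins) and robust summaries."""

    bin_edges_pct: np.ndarray
    frequencies: np.ndarray  # relative, sum to 1
    median_pct: float
    percentile_range_pct: tuple[float, float]  # [2.5th, 97.5th]
    n: int


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray
    voxel_count: int
    d_mean_gy: float
    d_max_gy: float
    d90_gy: float


# --------------------------------------------------------------------------
# gamma index
# --------------------------------------------------------------------------

def _search_offsets(crit: GammaCriteria) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic search lattice within the search radius, distance-sorted."""
    step = crit.step_mm
    n = int(np.floor(crit.radius_mm / step))
    ax = np.arange(-n, n + 1) * step
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    d = np.linalg.norm(offs, axis=1)
    keep = d <= crit.radius_mm + 1e-12
    offs, d = offs[keep], d[keep]
    order = np.argsort(d, kind="stable")
    return offs[order], d[order]


def _gamma_search(
    ref_points: np.ndarray,
    ref_doses: np.ndarray,
    eval_grid: DoseGrid,
    crit: GammaCriteria,
    batch: int = 512,
) -> np.ndarray:
    """Minimum gamma per reference point over the search lattice."""
    pts = np.asarray(ref_points, dtype=float).reshape(-1, 3)
    doses = np.asarray(ref_doses, dtype=float)
    if crit.mode == "local":
        dd_norm = doses * crit.dose_diff_pct / 100.0
    else:
        dd_norm = np.full(len(doses), crit.normalization_dose_gy * crit.dose_diff_pct / 100.0)

    offsets, dists = _search_offsets(crit)
    best = np.full(len(pts), np.inf)
    active = np.ones(len(pts), dtype=bool)
    for start in range(0, len(offsets), batch):
        sl = slice(start, min(start + batch, len(offsets)))
        # distance-sorted early exit: a remaining offset can only improve a
        # point whose current best exceeds its pure-distance gamma
        min_dist_term = (dists[sl.start] / crit.dta_mm) ** 2
        active &= best > min_dist_term
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        cand = pts[idx][:, None, :] + offsets[sl][None, :, :]
        vals = eval_grid.sample(cand.reshape(-1, 3)).reshape(len(idx), -1)
        with np.errstate(invalid="ignore"):
            g2 = ((vals - doses[idx][:, None]) / dd_norm[idx][:, None]) ** 2
            g2 = g2 + (dists[sl][None, :] / crit.dta_mm) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        best[idx] = np.minimum(best[idx], g2.min(axis=1))
    return np.sqrt(best)


def gamma_points(
    ref_points_mm: np.ndarray,
    ref_doses_gy: np.ndarray,
    eval_grid: DoseGrid,
    crit: GammaCriteria,
) -> GammaResult:
    """Gamma test for sparse reference points (e.g. OSLD measurements).

    Points outside the evaluated grid extent are excluded with a warning;
    the pass count is reported out of the evaluated points.
    """
    pts = np.asarray(ref_points_mm, dtype=float).reshape(-1, 3)
    doses = np.asarray(ref_doses_gy, dtype=float)
    keep = np.ones(len(pts), dtype=bool)
    if crit.low_cutoff_gy is not None:
        keep &= doses >= crit.low_cutoff_gy
    if crit.high_cutoff_gy is not None:
        keep &= doses <= crit.high_cutoff_gy
    inside = ~np.isnan(eval_grid.sample(pts))
    if np.any(keep & ~inside):
        warnings.warn(
            f"{int((keep & ~inside).sum())} reference point(s) outside the evaluated grid; excluded",
            stacklevel=2,
        )
    keep &= inside
    if not np.any(keep):
        raise EmptyComparisonError("no reference points survive the cutoffs/extent")
    gam = np.full(len(pts), np.nan)
    gam[keep] = _gamma_search(pts[keep], doses[keep], eval_grid, crit)
    evaluated = gam[keep]
    return GammaResult(gam, int((evaluated <= 1.0 + 1e-12).sum()), int(keep.sum()))


def gamma_map(ref: DoseGrid, eval_grid: DoseGrid, crit: GammaCriteria) -> GammaResult:
    """Gamma test over every reference voxel surviving the dose cutoffs.

    Returns a :class:`GammaResult` whose ``gamma`` field has the reference
    grid shape (NaN at voxels not evaluated).
    """
    doses = ref.values.ravel()
    keep = np.isfinite(doses)
    if crit.low_cutoff_gy is not None:
        keep &= doses >= crit.low_cutoff_gy
    if crit.high_cutoff_gy is not None:
        keep &= doses <= crit.high_cutoff_gy
    if ref.near_source_mask is not None:
        keep &= ~ref.near_source_mask.ravel()
    if not np.any(keep):
        raise EmptyComparisonError("no reference voxels survive the cutoffs")
    pts = ref.voxel_centers()[keep]
    gam_flat = np.full(doses.shape, np.nan)
    gam_flat[keep] = _gamma_search(pts, doses[keep], eval_grid, crit)
    evaluated = gam_flat[keep]
    return GammaResult(gam_flat.reshape(ref.values.shape),
                       int((evaluated <= 1.0 + 1e-12).sum()), int(keep.sum()))


# --------------------------------------------------------------------------
# dose differences, DVH, resampling
# --------------------------------------------------------------------------

def local_diff_map(ref: DoseGrid, eval_grid: DoseGrid) -> np.ndarray:
    """Signed local dose difference (%) on the reference lattice.

    (D_eval - D_ref) / D_ref * 100 with the evaluated dose trilinearly
    interpolated at the reference voxel centres; NaN where the reference dose
    is zero or the point falls outside the evaluated grid.
    """
    ev = eval_grid.sample(ref.voxel_centers()).reshape(ref.values.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = (ev - ref.values) / ref.values * 100.0
    diff[ref.values <= 0] = np.nan
    return diff


def diff_histogram(
    diff_pct: np.ndarray,
    ref: DoseGrid | None = None,
    low_cutoff_gy: float = 1.5,
    high_cutoff_gy: float | None = 24.0,
) -> DiffStats:
    """1%-bin relative-frequency histogram of local dose differences.

    Cutoffs apply to the *reference* dose: the low cutoff removes voxels far
    from the implant, the high cutoff the near-source voxels a TPS discards.
    """
    d = np.asarray(diff_pct, dtype=float).ravel()
    keep = np.isfinite(d)
    if ref is not None:
        rv = ref.values.ravel()
        keep &= rv >= low_cutoff_gy
        if high_cutoff_gy is not None:
            keep &= rv <= high_cutoff_gy
    d = d[keep]
    if d.size == 0:
        raise EmptyComparisonError("no voxels survive the cutoffs")
    lo = np.floor(d.min())
    hi = np.ceil(d.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.arange(lo, hi + 1.0, 1.0)
    counts, edges = np.histogram(d, bins=edges)
    freqs = counts / counts.sum()
    return DiffStats(
        bin_edges_pct=edges,
        frequencies=freqs,
        median_pct=float(np.median(d)),
        percentile_range_pct=(float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))),
        n=int(d.size),
    )


def compute_dvh(
    grid: DoseGrid, mask: np.ndarray, structure: str = "", bin_width_gy: float = 0.01
) -> DVH:
    """Cumulative DVH of the voxels selected by ``mask``.

    ``volume_pct[i]`` is the percent of structure volume receiving at least
    ``dose_gy[i]``; D90 is the dose covering 90% of the volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.values.shape:
        raise ValueError("mask shape must match the dose grid")
    doses = grid.values[mask]
    if doses.size == 0:
        raise EmptyComparisonError("empty structure mask")
    dmax = float(doses.max())
    axis = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    vol = np.array([(doses >= d).mean() for d in axis]) * 100.0
    d90 = float(np.interp(-90.0, -vol, axis))  # vol is non-increasing
    return DVH(
        structure=structure,
        dose_gy=axis,
        volume_pct=vol,
        voxel_count=int(doses.size),
        d_mean_gy=float(doses.mean()),
        d_max_gy=dmax,
        d90_gy=d90,
    )


def downsample_inplane(grid: DoseGrid, factor: int = 2) -> DoseGrid:
    """Block-mean the in-plane (x, y) resolution; slice spacing unchanged.

    Halving 0.27 mm CT-resolution dose grids to 0.54 mm in-plane voxels is
    the standard efficiency step before a voxelwise 3D comparison.  Edge
    rows/columns that do not fill a block are cropped with a warning.
    """
    if factor == 1:
        return DoseGrid(grid.origin_mm.copy(), grid.spacing_mm.copy(), grid.values.copy(),
                        None if grid.near_source_mask is None else grid.near_source_mask.copy())
    nz, ny, nx = grid.values.shape
    my, mx = ny // factor, nx // factor
    if my * factor != ny or mx * factor != nx:
        warnings.warn("in-plane dims not divisible by the factor; cropping the remainder",
                      stacklevel=2)
    v = grid.values[:, : my * factor, : mx * factor]
    v = v.reshape(nz, my, factor, mx, factor).mean(axis=(2, 4))
    spacing = grid.spacing_mm * np.array([factor, factor, 1.0])
    # origin moves to the centre of the first block
    origin = grid.origin_mm + (factor - 1) / 2.0 * np.array(
        [grid.spacing_mm[0], grid.spacing_mm[1], 0.0]
    )
    return DoseGrid(origin, spacing, v)
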