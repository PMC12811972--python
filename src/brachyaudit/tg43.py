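"""TG43 dose-to-water engine for an Ir-192 HDR line source.

Implements the AAPM TG43 2D formalism

    Ddot(r, theta) = Sk * Lambda * G_L(r, theta) / G_L(1 cm, 90 deg) * g(r) * F(r, theta)

with the line-source geometry function ``G_L``, a tabulated radial dose
function ``g(r)`` (linear interpolation in r) and a tabulated 2D anisotropy
function ``F(r, theta)`` (bilinear interpolation).  Multi-dwell plans are
superposed onto arbitrary axis-aligned grids or point sets.

Unit conventions (deliberate, enforced at the module boundary):

* internal TG43 math uses cm and hours (Sk in U = cGy cm^2 / h, dose rate in
  cGy/h);
* all public geometry is in mm (DICOM patient frame), dwell times in s, and
  accumulated dose in Gy.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "IR192_HALF_LIFE_DAYS",
    "CAPSULE_EXCLUSION_MM",
    "SourceModel",
    "DwellPosition",
    "Plan",
    "DoseGrid",
    "geometry_factor",
    "dose_rate",
    "accumulate_dose",
    "dose_at_points",
    "trak",
    "decay_correct",
    "load_default_source",
]

#: Ir-192 half life in days (literature value).
IR192_HALF_LIFE_DAYS = 73.83

#: Points closer than this to any dwell centre are flagged "near-source":
#: table data and the line-source model are unreliable inside the capsule
#: region, mirroring the near-source behaviour of clinical TPSs.
CAPSULE_EXCLUSION_MM = 1.0


class DomainError(ValueError):
    """Raised when a field point falls in a geometrically invalid region."""


class RangeError(ValueError):
    """Raised when a radius falls outside the tabulated range and
    extrapolation is disabled."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceModel:
    """Parameterization of an Ir-192 line source in TG43 terms.

    Parameters
    ----------
    air_kerma_strength:
        Sk in U = cGy cm^2 / h.
    dose_rate_constant:
        Lambda in cGy / (h * U).
    active_length_cm:
        Physical length L of the active core, cm.
    g_radii_cm, g_values:
        Radial dose function table; ``g(1 cm) == 1`` by normalization.
    f_radii_cm, f_angles_deg, f_values:
        2D anisotropy table, ``f_values[i, j] = F(f_radii_cm[i], f_angles_deg[j])``
        with angles tabulated on [0, 90] deg and mirrored for theta > 90.
    allow_extrapolation:
        If True, radii beyond the g-table maximum use inverse-square times
        the last tabulated g value; below the minimum the nearest entry is
        used.  Off by default: out-of-range radii raise :class:`RangeError`.
    reference_date:
        Calendar date at which ``air_kerma_strength`` applies.
    """

    air_kerma_strength: float
    dose_rate_constant: float
    active_length_cm: float
    g_radii_cm: np.ndarray
    g_values: np.ndarray
    f_radii_cm: np.ndarray
    f_angles_deg: np.ndarray
    f_values: np.ndarray
    allow_extrapolation: bool = False
    reference_date: _dt.date | None = None

    def __post_init__(self) -> None:
        for name in ("g_radii_cm", "g_values", "f_radii_cm", "f_angles_deg"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "f_values", np.asarray(self.f_values, dtype=float))
        if self.air_kerma_strength < 0:
            raise ValueError("Sk must be non-negative")
        if self.active_length_cm <= 0:
            raise ValueError("active length must be positive")
        if np.any(np.diff(self.g_radii_cm) <= 0):
            raise ValueError("g(r) radius grid must be strictly increasing")
        if np.any(np.diff(self.f_radii_cm) <= 0):
            raise ValueError("F(r, theta) radius grid must be strictly increasing")
        g1 = float(np.interp(1.0, self.g_radii_cm, self.g_values))
        if abs(g1 - 1.0) > 1e-6:
            raise ValueError(f"g(1 cm) = {g1!r} violates table normalization")
        j90 = int(np.argmin(np.abs(self.f_angles_deg - 90.0)))
        if abs(self.f_angles_deg[j90] - 90.0) > 1e-9 or np.any(
            np.abs(self.f_values[:, j90] - 1.0) > 1e-9
        ):
            raise ValueError("F(r, 90 deg) must equal 1 for every tabulated radius")

    @property
    def valid_radius_range_cm(self) -> tuple[float, float]:
        return float(self.g_radii_cm[0]), float(self.g_radii_cm[-1])

    # -- table interpolation ------------------------------------------------

    def radial_dose(self, r_cm: np.ndarray) -> np.ndarray:
        """g(r) with linear interpolation; extrapolation per policy."""
        r = np.asarray(r_cm, dtype=float)
        lo, hi = self.valid_radius_range_cm
        out_of_range = (r < lo) | (r > hi)
        if np.any(out_of_range) and not self.allow_extrapolation:
            bad = float(np.asarray(r)[out_of_range].flat[0])
            raise RangeError(
                f"radius {bad:.4g} cm outside tabulated g(r) range [{lo}, {hi}] cm "
                "and extrapolation is disabled"
            )
        g = np.interp(np.clip(r, lo, hi), self.g_radii_cm, self.g_values)
        return g

    def anisotropy(self, r_cm: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
        """F(r, theta) with bilinear interpolation; clamped at table edges.

        Angles are folded onto [0, 90] by the mirror symmetry of the source.
        """
        r = np.clip(np.asarray(r_cm, dtype=float), self.f_radii_cm[0], self.f_radii_cm[-1])
        th = np.asarray(theta_deg, dtype=float)
        th = np.where(th > 90.0, 180.0 - th, th)
        th = np.clip(th, self.f_angles_deg[0], self.f_angles_deg[-1])

        ri = np.clip(np.searchsorted(self.f_radii_cm, r) - 1, 0, len(self.f_radii_cm) - 2)
        ai = np.clip(np.searchsorted(self.f_angles_deg, th) - 1, 0, len(self.f_angles_deg) - 2)
        r0, r1 = self.f_radii_cm[ri], self.f_radii_cm[ri + 1]
        a0, a1 = self.f_angles_deg[ai], self.f_angles_deg[ai + 1]
        wr = (r - r0) / (r1 - r0)
        wa = (th - a0) / (a1 - a0)
        f00 = self.f_values[ri, ai]
        f01 = self.f_values[ri, ai + 1]
        f10 = self.f_values[ri + 1, ai]
        f11 = self.f_values[ri + 1, ai + 1]
        return (1 - wr) * ((1 - wa) * f00 + wa * f01) + wr * ((1 - wa) * f10 + wa * f11)


@dataclass(frozen=True)
class DwellPosition:
    """A single source dwell: centre and catheter tangent in mm (CT frame),
    dwell time in seconds."""

    center_mm: np.ndarray
    axis_direction: np.ndarray
    dwell_time_s: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center_mm, dtype=float).reshape(3)
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("axis_direction must be a unit vector")
            d = d / n
        if self.dwell_time_s < 0:
            raise ValueError("dwell_time must be non-negative")
        object.__setattr__(self, "center_mm", c)
        object.__setattr__(self, "axis_direction", d)


@dataclass
class Plan:
    """An ordered multi-catheter dwell sequence plus the source it drives.

    ``catheters`` maps catheter id -> ordered list of :class:`DwellPosition`.
    """

    catheters: dict[int, list[DwellPosition]]
    source: SourceModel
    prescription_dose_gy: float = 0.0
    prescription_points_mm: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    step_mm: float | None = None

    def __post_init__(self) -> None:
        self.prescription_points_mm = np.asarray(self.prescription_points_mm, dtype=float).reshape(-1, 3)
        for cid, dwells in self.catheters.items():
            if len(dwells) < 1:
                raise ValueError(f"catheter {cid} has no dwell positions")
            if self.step_mm is not None and len(dwells) > 1:
                centers = np.array([d.center_mm for d in dwells])
                gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
                if np.any(np.abs(gaps - self.step_mm) > 1e-6):
                    raise ValueError(
                        f"catheter {cid}: consecutive dwell spacing deviates from the "
                        f"declared step of {self.step_mm} mm"
                    )

    @property
    def dwells(self) -> list[DwellPosition]:
        out: list[DwellPosition] = []
        for cid in sorted(self.catheters):
            out.extend(self.catheters[cid])
        return out

    @property
    def total_time_s(self) -> float:
        return float(sum(d.dwell_time_s for d in self.dwells))

    def with_times(self, times_s: Sequence[float]) -> "Plan":
        """Return a copy with the flat dwell-time vector replaced."""
        times = list(map(float, times_s))
        if len(times) != len(self.dwells):
            raise ValueError("time vector length mismatch")
        cats: dict[int, list[DwellPosition]] = {}
        i = 0
        for cid in sorted(self.catheters):
            cats[cid] = []
            for d in self.catheters[cid]:
                cats[cid].append(DwellPosition(d.center_mm, d.axis_direction, times[i]))
                i += 1
        return Plan(cats, self.source, self.prescription_dose_gy,
                    self.prescription_points_mm.copy(), self.step_mm)


@dataclass
class DoseGrid:
    """Axis-aligned 3D dose field in Gy.

    ``values`` is indexed ``[iz, iy, ix]`` (slice, row, column); ``origin_mm``
    is the centre of voxel (0, 0, 0) and ``spacing_mm`` is ``(dx, dy, dz)``.
    """

    origin_mm: np.ndarray
    spacing_mm: np.ndarray
    values: np.ndarray
    near_source_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("grid spacing must be positive on all axes")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array indexed [iz, iy, ix]")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Voxel counts as (nx, ny, nz)."""
        nz, ny, nx = self.values.shape
        return nx, ny, nz

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (x, y, z) in mm."""
        nx, ny, nz = self.dims
        x = self.origin_mm[0] + self.spacing_mm[0] * np.arange(nx)
        y = self.origin_mm[1] + self.spacing_mm[1] * np.arange(ny)
        z = self.origin_mm[2] + self.spacing_mm[2] * np.arange(nz)
        return x, y, z

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of voxel centres in values order."""
        x, y, z = self.axis_coords()
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def sample(self, points_mm: np.ndarray, outside: float = np.nan) -> np.ndarray:
        """Trilinear interpolation of the dose at arbitrary points (mm).

        Points outside the grid extent return ``outside``.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        nx, ny, nz = self.dims
        # fractional index per axis
        fx = (pts[:, 0] - self.origin_mm[0]) / self.spacing_mm[0]
        fy = (pts[:, 1] - self.origin_mm[1]) / self.spacing_mm[1]
        fz = (pts[:, 2] - self.origin_mm[2]) / self.spacing_mm[2]
        inside = (
            (fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1)
            & (fz >= 0) & (fz <= nz - 1)
        )
        out = np.full(len(pts), outside, dtype=float)
        if not np.any(inside):
            return out
        fx, fy, fz = fx[inside], fy[inside], fz[inside]
        ix = np.clip(np.floor(fx).astype(int), 0, nx - 2) if nx > 1 else np.zeros(len(fx), int)
        iy = np.clip(np.floor(fy).astype(int), 0, ny - 2) if ny > 1 else np.zeros(len(fy), int)
        iz = np.clip(np.floor(fz).astype(int), 0, nz - 2) if nz > 1 else np.zeros(len(fz), int)
        tx = fx - ix
        ty = fy - iy
        tz = fz - iz
        v = self.values

        def at(dz, dy, dx):
            return v[
                np.minimum(iz + dz, nz - 1),
                np.minimum(iy + dy, ny - 1),
                np.minimum(ix + dx, nx - 1),
            ]

        acc = (
            at(0, 0, 0) * (1 - tz) * (1 - ty) * (1 - tx)
            + at(0, 0, 1) * (1 - tz) * (1 - ty) * tx
            + at(0, 1, 0) * (1 - tz) * ty * (1 - tx)
            + at(0, 1, 1) * (1 - tz) * ty * tx
            + at(1, 0, 0) * tz * (1 - ty) * (1 - tx)
            + at(1, 0, 1) * tz * (1 - ty) * tx
            + at(1, 1, 0) * tz * ty * (1 - tx)
            + at(1, 1, 1) * tz * ty * tx
        )
        out[inside] = acc
        return out


# --------------------------------------------------------------------------
# TG43 formalism
# --------------------------------------------------------------------------

_SIN_EPS = 1e-3  # below this sin(theta), the on-axis closed form is used


def geometry_factor(r_cm, theta_deg, active_length_cm: float):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    G_L = beta / (L * r * sin(theta)) off axis, 1 / (r^2 - L^2/4) on axis,
    and reduces to the point-source 1/r^2 as L -> 0.  ``r`` must place the
    point outside the active core (on-axis points require r > L/2).
    """
    r = np.asarray(r_cm, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    L = float(active_length_cm)
    scalar = r.ndim == 0 and th.ndim == 0
    r, th = np.atleast_1d(r), np.atleast_1d(th)
    r, th = np.broadcast_arrays(r, th)

    if np.any(r <= 0):
        raise DomainError("r must be positive")
    if L == 0.0:
        out = 1.0 / r**2
        return float(out[0]) if scalar else out.reshape(np.shape(r_cm))

    sin_th = np.sin(th)
    cos_th = np.cos(th)
    on_axis = np.abs(sin_th) < _SIN_EPS
    if np.any(on_axis & (r <= L / 2 + 1e-12)):
        raise DomainError("on-axis point inside the source capsule (r <= L/2)")

    out = np.empty_like(r)
    # off axis: subtended angle beta between the two source ends
    x = r * sin_th
    z = r * cos_th
    beta = np.arctan2(x, z - L / 2) - np.arctan2(x, z + L / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = beta / (L * r * sin_th)
    closed = 1.0 / (r**2 - L**2 / 4.0)
    out = np.where(on_axis, closed, out)
    if np.any(~np.isfinite(out) | (out <= 0)):
        raise DomainError("geometry factor evaluated to a non-finite or non-positive value")
    return float(out[0]) if scalar else out.reshape(np.shape(r_cm))


def _polar_coords(points_mm: np.ndarray, dwell: DwellPosition) -> tuple[np.ndarray, np.ndarray]:
    """(r [cm], theta [deg]) of each point relative to a dwell."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    d = pts - dwell.center_mm
    r_mm = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_th = np.clip(d @ dwell.axis_direction / np.where(r_mm == 0, 1.0, r_mm), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_th))
    return r_mm / 10.0, theta


def dose_rate(source: SourceModel, dwell: DwellPosition, points_mm) -> np.ndarray | float:
    """TG43 dose rate in cGy/h at one or many field points (mm, CT frame)."""
    pts = np.asarray(points_mm, dtype=float)
    scalar = pts.ndim == 1
    r_cm, theta = _polar_coords(pts, dwell)
    if np.any(r_cm * 10.0 < CAPSULE_EXCLUSION_MM):
        raise DomainError(
            f"field point within the {CAPSULE_EXCLUSION_MM} mm capsule exclusion region"
        )
    rate = _dose_rate_rtheta(source, r_cm, theta)
    return float(rate[0]) if scalar else rate


def _dose_rate_rtheta(
    source: SourceModel, r_cm: np.ndarray, theta_deg: np.ndarray, clamp_radius: bool = False
) -> np.ndarray:
    """TG43 product formula on (r, theta) arrays; cGy/h."""
    L = source.active_length_cm
    r = np.asarray(r_cm, dtype=float)
    if clamp_radius:
        lo, hi = source.valid_radius_range_cm
        r = np.clip(r, max(lo, L / 2 * 1.01), hi)
    gl_ref = geometry_factor(1.0, 90.0, L)
    gl = geometry_factor(r, theta_deg, L)
    g = source.radial_dose(r)
    f = source.anisotropy(r, theta_deg)
    return source.air_kerma_strength * source.dose_rate_constant * gl / gl_ref * g * f


def dose_at_points(plan: Plan, points_mm, near_source: str = "clamp") -> np.ndarray:
    """Accumulated dose in Gy from all dwells at arbitrary points (mm).

    ``near_source`` controls points inside the capsule-exclusion region of any
    dwell: ``"clamp"`` evaluates with the radius clamped to the table minimum
    (finite, unreliable), ``"error"`` raises, ``"nan"`` returns NaN there.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    dose_cgy_h_s = np.zeros(len(pts))
    flagged = np.zeros(len(pts), dtype=bool)
    for dwell in plan.dwells:
        r_cm, theta = _polar_coords(pts, dwell)
        near = r_cm * 10.0 < CAPSULE_EXCLUSION_MM
        flagged |= near
        if dwell.dwell_time_s == 0.0:
            continue
        rate = _dose_rate_rtheta(plan.source, r_cm, theta, clamp_radius=True)
        dose_cgy_h_s += rate * dwell.dwell_time_s
    if np.any(flagged):
        if near_source == "error":
            raise DomainError("points inside the near-source exclusion region")
        if near_source == "nan":
            dose_cgy_h_s[flagged] = np.nan
    # cGy/h * s -> Gy
    return dose_cgy_h_s / 3600.0 / 100.0


def accumulate_dose(
    plan: Plan,
    origin_mm,
    spacing_mm,
    dims,
    chunk_voxels: int = 2_000_000,
) -> DoseGrid:
    """Superpose all dwells onto an axis-aligned grid.

    ``dims`` is (nx, ny, nz).  Voxels within the capsule-exclusion radius of
    any dwell centre are flagged in ``near_source_mask`` (their values are the
    clamped-table evaluation, not poisoned).  Dose is linear in dwell times.
    """
    origin = np.asarray(origin_mm, dtype=float).reshape(3)
    spacing = np.asarray(spacing_mm, dtype=float).reshape(3)
    nx, ny, nz = (int(d) for d in dims)
    grid = DoseGrid(origin, spacing, np.zeros((nz, ny, nx)))
    if not plan.dwells or plan.total_time_s == 0.0:
        if not plan.dwells:
            warnings.warn("empty plan: returning an all-zero dose grid", stacklevel=2)

    centers = grid.voxel_centers()
    n = len(centers)
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    for start in range(0, n, chunk_voxels):
        sl = slice(start, min(start + chunk_voxels, n))
        pts = centers[sl]
        acc = np.zeros(sl.stop - sl.start)
        for dwell in plan.dwells:
            r_cm, theta = _polar_coords(pts, dwell)
            mask[sl] |= r_cm * 10.0 < CAPSULE_EXCLUSION_MM
            if dwell.dwell_time_s == 0.0:
                continue
            acc += _dose_rate_rtheta(plan.source, r_cm, theta, clamp_radius=True) * dwell.dwell_time_s
        values[sl] = acc / 3600.0 / 100.0
    grid.values = values.reshape(nz, ny, nx)
    grid.near_source_mask = mask.reshape(nz, ny, nx)
    return grid


def trak(plan: Plan) -> float:
    """Total Reference Air Kerma in U*h: Sk times total dwell time in hours."""
    return plan.source.air_kerma_strength * plan.total_time_s / 3600.0


def decay_correct(sk0: float, elapsed_days: float, half_life_days: float = IR192_HALF_LIFE_DAYS) -> float:
    """Air-kerma strength after ``elapsed_days`` of radioactive decay."""
    if half_life_days <= 0:
        raise ValueError("half life must be positive")
    return sk0 * 2.0 ** (-elapsed_days / half_life_days)


# --------------------------------------------------------------------------
# bundled source data
# --------------------------------------------------------------------------

def _read_csv_lines(name: str) -> list[list[str]]:
    text = resources.files("brachyaudit.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([c.strip() for c in line.split(",")])
    return rows


def load_default_source(
    air_kerma_strength: float = 12765.5,
    dose_rate_constant: float = 1.109,
    allow_extrapolation: bool = False,
) -> SourceModel:
    """Generic Ir-192 line source (L = 3.5 mm) with the bundled consensus-style
    g(r) and F(r, theta) tables.

    The default Sk of 12765.5 U matches the pilot-study source on its
    treatment day; Lambda = 1.109 cGy/(h*U) is a class value for Ir-192
    line sources.
    """
    g_rows = _read_csv_lines("ir192_radial_dose.csv")
    assert g_rows[0] == ["radius_cm", "g"]
    g_radii = np.array([float(r[0]) for r in g_rows[1:]])
    g_vals = np.array([float(r[1]) for r in g_rows[1:]])

    f_rows = _read_csv_lines("ir192_anisotropy.csv")
    f_angles = np.array([float(a) for a in f_rows[0][1:]])
    f_radii = np.array([float(r[0]) for r in f_rows[1:]])
    f_vals = np.array([[float(v) for v in r[1:]] for r in f_rows[1:]])

    return SourceModel(
        air_kerma_strength=air_kerma_strength,
        dose_rate_constant=dose_rate_constant,
        active_length_cm=0.35,
        g_radii_cm=g_radii,
        g_values=g_vals,
        f_radii_cm=f_radii,
        f_angles_deg=f_angles,
        f_values=f_vals,
        allow_extrapolation=allow_extrapolation,
    )
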