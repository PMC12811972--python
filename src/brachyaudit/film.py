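"""Radiochromic-film dosimetry pipeline.

Covers the measurement branch that turns scanned film images into absolute
2D dose maps registered to the planning-CT frame:

* per-channel calibration of the net-optical-density (netOD) response with
  the power-law form ``dose = p1 * netOD + p2 * netOD**p3`` (a generic
  Devic-style triple-channel calibration);
* scan-to-dose conversion with an inverse-variance-weighted combination of
  the three channel inversions and a low-dose validity mask;
* sub-pixel localization of the pin holes punched through each film and of
  the corresponding metal pins in the CT stack;
* closed-form rigid 2D/3D registration of the film plane into the CT frame
  from the three matched fiducials (with the scan-face flip hypothesis
  tested), reporting the fiducial registration error (FRE);
* resampling of the registered dose map at CT-frame target positions.

Film frame convention: origin at the scan's top-left pixel centre, x
rightward along columns, y downward along rows, mm units.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "FilmScan",
    "CalibrationCurve",
    "FiducialCorrespondence",
    "RigidFilmTransform",
    "CalibrationError",
    "DetectionError",
    "AmbiguousCorrespondenceError",
    "fit_calibration",
    "film_to_dose",
    "detect_pin_holes",
    "detect_pins_ct",
    "solve_registration",
    "resample_to_ct",
    "write_scan_tiff",
    "read_scan_tiff",
    "LOW_DOSE_CUTOFF_GY",
    "SCANNER_WHITE",
]

#: Film areas below this dose carry too much calibration uncertainty in the
#: Ir-192 quality when calibrated at 6 MV; they are masked, not deleted.
LOW_DOSE_CUTOFF_GY = 1.5

#: 16-bit transmission value of unattenuated scanner backlight (a pin hole).
SCANNER_WHITE = 65000


class CalibrationError(ValueError):
    pass


class DetectionError(ValueError):
    pass


class AmbiguousCorrespondenceError(ValueError):
    pass


def _cross2(a, b) -> float:
    """z-component of the cross product of two 2-vectors."""
    return float(a[0] * b[1] - a[1] * b[0])


@dataclass
class FilmScan:
    """A scanned film piece: 16-bit RGB pixels plus scan geometry."""

    pixels: np.ndarray  # (rows, cols, 3) uint16
    pixel_spacing_mm: float
    plane_id: str = ""
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (rows, cols, 3)")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass
class CalibrationCurve:
    """Per-channel netOD power-law response ``d = p1*x + p2*x**p3``.

    ``unexposed_pv`` holds the zero-dose transmission value per channel; the
    response must be strictly monotone over ``dose_range_gy``.
    """

    params: np.ndarray  # (3 channels, 3 params)
    unexposed_pv: np.ndarray  # (3,)
    dose_range_gy: tuple[float, float] = (0.0, 14.0)
    fit_residuals_gy: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).reshape(3, 3)
        self.unexposed_pv = np.asarray(self.unexposed_pv, dtype=float).reshape(3)

    def dose_from_netod(self, netod, channel: int) -> np.ndarray:
        p1, p2, p3 = self.params[channel]
        x = np.clip(np.asarray(netod, dtype=float), 0.0, None)
        return p1 * x + p2 * np.power(x, p3)

    def sensitivity(self, netod, channel: int) -> np.ndarray:
        """d(dose)/d(netOD); used for inverse-variance channel weighting."""
        p1, p2, p3 = self.params[channel]
        x = np.clip(np.asarray(netod, dtype=float), 1e-6, None)
        return p1 + p2 * p3 * np.power(x, p3 - 1.0)

    def max_netod(self, channel: int) -> float:
        """netOD at the top of the valid dose range (monotone inversion bound)."""
        hi = self.dose_range_gy[1]
        f = lambda x: float(self.dose_from_netod(x, channel)) - hi
        x = 1.0
        while f(x) < 0:
            x *= 2.0
            if x > 64:
                raise CalibrationError("response does not reach the top of the dose range")
        return optimize.brentq(f, 0.0, x)

    def netod_from_dose(self, dose, channel: int, n_grid: int = 4096) -> np.ndarray:
        """Inverse of the per-channel response via a dense monotone grid."""
        xmax = self.max_netod(channel)
        xs = np.linspace(0.0, xmax, n_grid)
        ds = self.dose_from_netod(xs, channel)
        d = np.clip(np.asarray(dose, dtype=float), 0.0, float(ds[-1]))
        return np.interp(d, ds, xs)


def write_scan_tiff(scan: FilmScan, path) -> None:
    """Write a scan as 16-bit RGB TIFF with its dpi in the resolution tags."""
    import tifffile

    dpi = 25.4 / scan.pixel_spacing_mm
    tifffile.imwrite(path, scan.pixels, resolution=(dpi, dpi),
                     resolutionunit="INCH", photometric="rgb")


def read_scan_tiff(path, plane_id: str = "", n_averaged: int = 1) -> FilmScan:
    """Read a 16-bit RGB TIFF scan, taking the pixel pitch from its tags."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        res = page.tags.get("XResolution")
        if res is None:
            raise ValueError("scan TIFF carries no resolution tag")
        num, den = res.value
        spacing = 25.4 * den / num  # pixels per inch -> mm per pixel
    return FilmScan(pixels, spacing, plane_id=plane_id, n_averaged=n_averaged)


def fit_calibration(
    pv_means: np.ndarray,
    doses_gy: np.ndarray,
    dose_range_gy: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Fit the per-channel calibration from irradiated calibration pieces.

    ``pv_means`` is (n_pieces, 3): the mean ROI transmission value of each
    scanned piece per channel; ``doses_gy`` the delivered doses.  The design
    must include an unirradiated piece (the channel zero-light reference) and
    at least four dose levels.  The default protocol uses 12 pieces over
    0-14 Gy.
    """
    pv = np.asarray(pv_means, dtype=float)
    doses = np.asarray(doses_gy, dtype=float)
    if pv.shape[0] != len(doses):
        raise ValueError("one PV row per dose level required")
    if len(np.unique(np.round(doses, 6))) < 4:
        raise CalibrationError("at least four distinct dose levels required")
    i0 = int(np.argmin(doses))
    if doses[i0] > 1e-9:
        raise CalibrationError("an unirradiated (0 Gy) piece is required")
    pv0 = pv[i0]

    params = np.zeros((3, 3))
    residuals = np.zeros((len(doses), 3))
    for ch in range(3):
        netod = np.log10(pv0[ch] / pv[:, ch])
        if np.any(np.diff(netod[np.argsort(doses)]) <= -1e-6):
            raise CalibrationError(f"channel {ch}: netOD response is not monotone in dose")
        model = lambda x, p1, p2, p3: p1 * x + p2 * np.power(np.clip(x, 0, None), p3)
        p0 = (max(doses) / max(netod.max(), 1e-3), 1.0, 2.5)
        popt, _ = optimize.curve_fit(
            model, netod, doses, p0=p0,
            bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 6.0]), maxfev=20000,
        )
        params[ch] = popt
        residuals[:, ch] = model(netod, *popt) - doses
    rng = dose_range_gy or (float(doses.min()), float(doses.max()))
    return CalibrationCurve(params, pv0, rng, residuals)


def film_to_dose(
    scan: FilmScan,
    curve: CalibrationCurve,
    low_cutoff_gy: float = LOW_DOSE_CUTOFF_GY,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Convert a scan to a 2D dose map (Gy).

    Returns (dose, low_dose_mask, report).  Each channel is inverted through
    its calibration and the three estimates are combined with inverse-variance
    weights (variance from the channel sensitivity at the local netOD, for a
    common netOD noise level).  Pixels below ``low_cutoff_gy`` are flagged in
    the mask but retained.  Pixels beyond the calibration dose range are
    clipped and counted in the report.
    """
    px = scan.pixels.astype(float)
    hi = curve.dose_range_gy[1]
    doses = np.zeros(px.shape[:2] + (3,))
    weights = np.zeros_like(doses)
    clipped = 0
    for ch in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            netod = np.log10(curve.unexposed_pv[ch] / np.clip(px[:, :, ch], 1.0, None))
        netod = np.clip(netod, 0.0, None)
        d = curve.dose_from_netod(netod, ch)
        over = d > hi
        clipped += int(over.sum())
        doses[:, :, ch] = np.clip(d, 0.0, hi)
        sens = curve.sensitivity(netod, ch)
        weights[:, :, ch] = 1.0 / np.square(sens)
    dose = (doses * weights).sum(axis=2) / weights.sum(axis=2)
    mask = dose < low_cutoff_gy
    report = {"n_clipped": clipped, "n_pixels": int(dose.size)}
    return dose, mask, report


# --------------------------------------------------------------------------
# fiducial detection
# --------------------------------------------------------------------------

def detect_pin_holes(
    scan: FilmScan,
    expected: int = 3,
    rel_threshold: float = 0.85,
    area_bounds_mm2: tuple[float, float] = (0.2, 6.0),
) -> np.ndarray:
    """Sub-pixel centres of the pin holes on a film scan, film frame mm.

    Holes transmit the full scanner backlight and are the brightest features
    of a transmission scan; detection thresholds at ``rel_threshold`` times
    the image maximum (invariant to global intensity scaling), filters
    components by area, and returns intensity-weighted centroids ordered by
    (y, then x).
    """
    inten = scan.pixels.astype(float).sum(axis=2)
    thr = rel_threshold * float(inten.max())
    labels, nlab = ndimage.label(inten > thr)
    pix_area = scan.pixel_spacing_mm**2
    found = []
    for lab in range(1, nlab + 1):
        mask = labels == lab
        area = mask.sum() * pix_area
        if not (area_bounds_mm2[0] <= area <= area_bounds_mm2[1]):
            continue
        w = inten[mask] - thr
        idx = np.argwhere(mask).astype(float)  # (row, col)
        com = (idx * w[:, None]).sum(axis=0) / w.sum()
        found.append((com[1] * scan.pixel_spacing_mm, com[0] * scan.pixel_spacing_mm))
    if len(found) != expected:
        raise DetectionError(f"found {len(found)} hole candidates, expected {expected}")
    pts = np.array(found)
    return pts[np.lexsort((pts[:, 0], pts[:, 1]))]


def detect_pins_ct(
    ct,
    film_plane_offset_mm: float,
    pin_threshold_hu: float = 2500.0,
    plane_tolerance_mm: float = 2.0,
    expected: int = 3,
) -> np.ndarray:
    """Centroids of the metal pins near a film plane in the CT stack (mm)."""
    hu = np.asarray(ct.values, dtype=float)
    spacing = np.asarray(ct.spacing_mm, dtype=float)
    labels, nlab = ndimage.label(hu > pin_threshold_hu)
    found = []
    for lab in range(1, nlab + 1):
        mask = labels == lab
        w = hu[mask] - pin_threshold_hu
        idx = np.argwhere(mask).astype(float)
        if w.sum() <= 0:
            w = np.ones(len(idx))
        com = (idx * w[:, None]).sum(axis=0) / w.sum()
        xyz = ct.origin_mm + spacing * com[::-1]
        if abs(xyz[1] - film_plane_offset_mm) <= plane_tolerance_mm:
            found.append(xyz)
    if len(found) != expected:
        raise DetectionError(f"found {len(found)} pin candidates near the plane, expected {expected}")
    pts = np.array(found)
    return pts[np.lexsort((pts[:, 0], pts[:, 2]))]


# --------------------------------------------------------------------------
# rigid registration
# --------------------------------------------------------------------------

@dataclass
class FiducialCorrespondence:
    """Matched film-frame and CT-frame fiducial triples."""

    film_points_mm: np.ndarray  # (3, 2)
    ct_points_mm: np.ndarray  # (3, 3)
    order: tuple[int, ...] = (0, 1, 2)
    fre_mm: float | None = None

    def __post_init__(self) -> None:
        self.film_points_mm = np.asarray(self.film_points_mm, dtype=float).reshape(3, 2)
        self.ct_points_mm = np.asarray(self.ct_points_mm, dtype=float).reshape(3, 3)
        a, b, c = self.film_points_mm
        area = 0.5 * abs(_cross2(b - a, c - a))
        if area < 1.0:
            raise ValueError("fiducial triple is (near-)collinear")


@dataclass
class RigidFilmTransform:
    """Rigid placement of the film plane into the CT frame.

    Maps film coordinates (u, v) to CT in-plane coordinates (x, z) on the
    plane ``y = plane_offset_mm``:  ``[x, z] = R @ flip([u, v]) + t`` where
    ``flip`` negates u when the film was scanned face-down.
    """

    rotation: np.ndarray  # (2, 2), det = +1
    translation: np.ndarray  # (2,)
    plane_offset_mm: float
    flip: bool = False
    fre_mm: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be orthonormal with det +1")

    @property
    def angle_deg(self) -> float:
        return math.degrees(math.atan2(self.rotation[1, 0], self.rotation[0, 0]))

    def _flip(self, pts2d: np.ndarray) -> np.ndarray:
        if not self.flip:
            return pts2d
        out = pts2d.copy()
        out[:, 0] = -out[:, 0]
        return out

    def film_to_ct(self, film_pts_mm: np.ndarray) -> np.ndarray:
        """(N, 2) film points -> (N, 3) CT points on the film plane."""
        p = self._flip(np.atleast_2d(np.asarray(film_pts_mm, dtype=float)))
        xz = p @ self.rotation.T + self.translation
        out = np.empty((len(xz), 3))
        out[:, 0] = xz[:, 0]
        out[:, 1] = self.plane_offset_mm
        out[:, 2] = xz[:, 1]
        return out

    def ct_to_film(self, ct_pts_mm: np.ndarray) -> np.ndarray:
        """(N, 3) CT points -> (N, 2) film coordinates (plane projection)."""
        p = np.atleast_2d(np.asarray(ct_pts_mm, dtype=float))
        xz = np.stack([p[:, 0], p[:, 2]], axis=1)
        uv = (xz - self.translation) @ self.rotation
        return self._flip(uv)


def _kabsch_2d(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit dst ~= R @ src + t (rotation only, det +1)."""
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    t = dst.mean(axis=0) - r @ src.mean(axis=0)
    res = src @ r.T + t - dst
    fre = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return r, t, fre


def solve_registration(
    film_points_mm: np.ndarray,
    ct_points_mm: np.ndarray,
    match_tolerance_mm: float = 0.5,
) -> tuple[RigidFilmTransform, FiducialCorrespondence]:
    """Resolve the fiducial correspondence and fit the rigid transform.

    The correspondence between the three hole centres (film frame) and the
    three pin centroids (CT frame) is resolved by matching the pairwise
    distance patterns of the two triangles within ``match_tolerance_mm``;
    because pairwise distances cannot distinguish a mirrored scan, the flip
    hypothesis is decided from the triangle orientations.  The rigid fit is
    the closed-form 2D least-squares (Kabsch) solution; the FRE is the RMS
    fiducial residual.
    """
    film = np.asarray(film_points_mm, dtype=float).reshape(3, 2)
    ct3 = np.asarray(ct_points_mm, dtype=float).reshape(3, 3)
    plane_offset = float(ct3[:, 1].mean())
    ct = np.stack([ct3[:, 0], ct3[:, 2]], axis=1)

    def sides(pts):
        return np.array([
            np.linalg.norm(pts[1] - pts[2]),
            np.linalg.norm(pts[2] - pts[0]),
            np.linalg.norm(pts[0] - pts[1]),
        ])

    film_sides = sides(film)
    candidates = []
    for perm in itertools.permutations(range(3)):
        ct_perm = ct[list(perm)]
        if np.max(np.abs(sides(ct_perm) - film_sides)) > match_tolerance_mm:
            continue
        orient_f = np.sign(_cross2(film[1] - film[0], film[2] - film[0]))
        orient_c = np.sign(_cross2(ct_perm[1] - ct_perm[0], ct_perm[2] - ct_perm[0]))
        flip = orient_f != orient_c
        src = film.copy()
        if flip:
            src[:, 0] = -src[:, 0]
        r, t, fre = _kabsch_2d(src, ct_perm)
        candidates.append((fre, perm, flip, r, t))
    if not candidates:
        raise DetectionError("no fiducial correspondence matches the distance pattern")
    candidates.sort(key=lambda c: c[0])
    distinct = {c[1] for c in candidates}
    if len(distinct) > 1 and candidates[1][0] - candidates[0][0] < 1e-6:
        raise AmbiguousCorrespondenceError(
            "fiducial triangle is too symmetric to resolve the correspondence: "
            + "; ".join(f"order {c[1]} flip={c[2]} FRE={c[0]:.4f} mm" for c in candidates[:2])
        )
    fre, perm, flip, r, t = candidates[0]
    transform = RigidFilmTransform(r, t, plane_offset, flip=flip, fre_mm=fre)
    corr = FiducialCorrespondence(film, ct3[list(perm)], order=perm, fre_mm=fre)
    return transform, corr


def resample_to_ct(
    dose_map: np.ndarray,
    pixel_spacing_mm: float,
    transform: RigidFilmTransform,
    target_points_mm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a film dose map at CT-frame target positions.

    Returns (values, missing) where values are bilinear interpolations of the
    dose map at the film coordinates of each target point and ``missing``
    flags points outside the film extent (excluded from comparisons).
    """
    uv = transform.ct_to_film(target_points_mm)
    rows = uv[:, 1] / pixel_spacing_mm
    cols = uv[:, 0] / pixel_spacing_mm
    h, w = dose_map.shape
    missing = (rows < 0) | (rows > h - 1) | (cols < 0) | (cols > w - 1)
    vals = ndimage.map_coordinates(
        np.asarray(dose_map, dtype=float), np.stack([rows, cols]),
        order=1, mode="constant", cval=np.nan,
    )
    vals[missing] = np.nan
    return vals, missing
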