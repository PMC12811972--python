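"""Readers and writers for the DICOM-RT dialects the audit workflow touches.

A deliberately minimal, conformant subset is supported: a single frame of
reference, axis-aligned orientation, HDR brachytherapy plans whose channels
carry 3D control points with cumulative time weights, and integer-scaled RT
Dose grids.  Anything outside the subset raises
:class:`UnsupportedDialectError` instead of guessing.  Dwell times are
decoded from cumulative weights scaled by the channel total time, which
transparently supports both weight-encoded and absolute-seconds channels.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import tg43
from .phantom import CTStack

__all__ = [
    "ParseError",
    "UnsupportedDialectError",
    "write_rtplan",
    "read_rtplan",
    "write_rtdose",
    "read_rtdose",
    "write_ct_series",
    "read_ct_series",
]

_RTPLAN_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_CT_CLASS = "1.2.840.10008.5.1.4.1.1.2"


class ParseError(ValueError):
    pass


class UnsupportedDialectError(ValueError):
    pass


def _base_dataset(sop_class: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    now = datetime.datetime(2000, 1, 1)  # fixed timestamps keep outputs reproducible
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.PatientName = "AUDIT^PHANTOM"
    ds.PatientID = "AUDIT"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    return ds


# --------------------------------------------------------------------------
# RT Plan
# --------------------------------------------------------------------------

def write_rtplan(plan: tg43.Plan, path: str | Path) -> None:
    """Serialize a brachytherapy plan: per-channel control points with
    cumulative time weights in seconds, plus the air-kerma strength."""
    ds = _base_dataset(_RTPLAN_CLASS)
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "brachyaudit"
    ds.BrachyTreatmentTechnique = "INTERSTITIAL"
    ds.BrachyTreatmentType = "HDR"

    src = Dataset()
    src.SourceNumber = 1
    src.SourceType = "LINE"
    src.SourceIsotopeName = "Ir-192"
    src.ReferenceAirKermaRate = float(plan.source.air_kerma_strength)
    src.ActiveSourceLength = plan.source.active_length_cm * 10.0
    ds.SourceSequence = [src]

    if plan.prescription_dose_gy:
        ref = Dataset()
        ref.DoseReferenceNumber = 1
        ref.DoseReferenceStructureType = "COORDINATES"
        ref.TargetPrescriptionDose = float(plan.prescription_dose_gy)
        ds.DoseReferenceSequence = [ref]

    setup = Dataset()
    setup.ApplicationSetupType = "FLETCHER_SUIT"
    setup.ApplicationSetupNumber = 1
    channels = []
    for cid in sorted(plan.catheters):
        dwells = plan.catheters[cid]
        ch = Dataset()
        ch.ChannelNumber = cid
        total = float(sum(d.dwell_time_s for d in dwells))
        ch.ChannelTotalTime = total
        ch.FinalCumulativeTimeWeight = total
        ch.SourceApplicatorStepSize = plan.step_mm if plan.step_mm else 0.0
        ch.NumberOfControlPoints = 2 * len(dwells)
        ch.ReferencedSourceNumber = 1
        cps = []
        cum = 0.0
        for i, d in enumerate(dwells):
            for half in (0, 1):
                cp = Dataset()
                cp.ControlPointIndex = 2 * i + half
                cp.ControlPoint3DPosition = [float(v) for v in d.center_mm]
                if half == 1:
                    cum += d.dwell_time_s
                cp.CumulativeTimeWeight = cum
                cps.append(cp)
        ch.BrachyControlPointSequence = cps
        channels.append(ch)
    setup.ChannelSequence = channels
    ds.ApplicationSetupSequence = [setup]
    ds.save_as(path, enforce_file_format=True)


def read_rtplan(path: str | Path, source: tg43.SourceModel | None = None) -> tg43.Plan:
    """Reconstruct a :class:`~brachyaudit.tg43.Plan` from an RT Plan file.

    Dwell times come from consecutive cumulative-weight increments scaled by
    ``ChannelTotalTime / FinalCumulativeTimeWeight``; the catheter tangent is
    taken from the channel's control-point geometry.  ``source`` supplies the
    TG43 tables (the file only carries Sk).
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTPLAN":
        raise ParseError("not an RT Plan file")
    try:
        sk = float(ds.SourceSequence[0].ReferenceAirKermaRate)
    except (AttributeError, IndexError) as exc:
        raise ParseError("missing SourceSequence/ReferenceAirKermaRate") from exc
    base = source or tg43.load_default_source()
    src = tg43.SourceModel(
        air_kerma_strength=sk,
        dose_rate_constant=base.dose_rate_constant,
        active_length_cm=base.active_length_cm,
        g_radii_cm=base.g_radii_cm,
        g_values=base.g_values,
        f_radii_cm=base.f_radii_cm,
        f_angles_deg=base.f_angles_deg,
        f_values=base.f_values,
        allow_extrapolation=base.allow_extrapolation,
    )
    prescription = 0.0
    if getattr(ds, "DoseReferenceSequence", None):
        prescription = float(
            getattr(ds.DoseReferenceSequence[0], "TargetPrescriptionDose", 0.0)
        )

    catheters: dict[int, list[tg43.DwellPosition]] = {}
    step = None
    try:
        channel_seq = ds.ApplicationSetupSequence[0].ChannelSequence
    except (AttributeError, IndexError) as exc:
        raise ParseError("missing ApplicationSetupSequence/ChannelSequence") from exc
    for ch in channel_seq:
        cid = int(ch.ChannelNumber)
        cps = ch.BrachyControlPointSequence
        if any(not hasattr(cp, "CumulativeTimeWeight") for cp in cps):
            raise ParseError("control point missing CumulativeTimeWeight")
        positions = np.array([[float(v) for v in cp.ControlPoint3DPosition] for cp in cps])
        weights = np.array([float(cp.CumulativeTimeWeight) for cp in cps])
        final_w = float(getattr(ch, "FinalCumulativeTimeWeight", weights[-1]) or 0.0)
        total = float(getattr(ch, "ChannelTotalTime", 0.0) or 0.0)
        scale = total / final_w if final_w > 0 else 0.0
        if getattr(ch, "SourceApplicatorStepSize", None):
            step = float(ch.SourceApplicatorStepSize)
        # dwell = consecutive control-point pair at the same position
        span = positions[-1] - positions[0]
        norm = np.linalg.norm(span)
        direction = span / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        dwells = []
        for i in range(0, len(cps) - 1, 2):
            t = (weights[i + 1] - weights[i]) * scale
            dwells.append(tg43.DwellPosition(positions[i], direction, max(t, 0.0)))
        catheters[cid] = dwells
    return tg43.Plan(catheters, src, prescription, step_mm=step)


# --------------------------------------------------------------------------
# RT Dose
# --------------------------------------------------------------------------

def write_rtdose(grid: tg43.DoseGrid, path: str | Path) -> None:
    """Serialize a dose grid as an integer-scaled RT Dose volume.

    The grid scaling is chosen from the dose maximum so quantization error
    stays below 1e-4 Gy.
    """
    if grid.values.size == 0:
        raise ValueError("cannot write an empty dose grid")
    ds = _base_dataset(_RTDOSE_CLASS)
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nz, ny, nx = grid.values.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.ImagePositionPatient = [float(v) for v in grid.origin_mm]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(grid.spacing_mm[1]), float(grid.spacing_mm[0])]
    ds.GridFrameOffsetVector = [float(i * grid.spacing_mm[2]) for i in range(nz)]
    ds.SliceThickness = float(grid.spacing_mm[2])
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    dmax = float(grid.values.max())
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1e-8
    ds.DoseGridScaling = scaling
    ints = np.rint(grid.values / scaling).astype(np.uint32)
    ds.PixelData = ints.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_rtdose(path: str | Path) -> tg43.DoseGrid:
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ParseError("not an RT Dose file")
    iop = [float(v) for v in ds.ImageOrientationPatient]
    if np.max(np.abs(np.array(iop) - np.array([1, 0, 0, 0, 1, 0]))) > 1e-6:
        raise UnsupportedDialectError("only axis-aligned dose grids are supported")
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else float(
        getattr(ds, "SliceThickness", 1.0) or 1.0
    )
    if len(offsets) > 2 and np.max(np.abs(np.diff(offsets) - dz)) > 1e-6:
        raise UnsupportedDialectError("non-uniform frame offsets are not supported")
    spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
    origin = np.array([float(v) for v in ds.ImagePositionPatient])
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if values.ndim == 2:
        values = values[None, :, :]
    return tg43.DoseGrid(origin, spacing, values)


# --------------------------------------------------------------------------
# CT series
# --------------------------------------------------------------------------

def write_ct_series(ct: CTStack, directory: str | Path) -> list[Path]:
    """Write a synthetic CT stack as one file per slice (HU stored directly)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = ct.values.shape
    series_uid = generate_uid()
    frame_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for iz in range(nz):
        ds = _base_dataset(_CT_CLASS)
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = iz + 1
        ds.Rows = ny
        ds.Columns = nx
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z = float(ct.origin_mm[2] + iz * ct.spacing_mm[2])
        ds.ImagePositionPatient = [float(ct.origin_mm[0]), float(ct.origin_mm[1]), z]
        ds.SliceThickness = float(ct.spacing_mm[2])
        ds.PixelSpacing = [float(ct.spacing_mm[1]), float(ct.spacing_mm[0])]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.ascontiguousarray(ct.values[iz].astype(np.int16)).tobytes()
        p = directory / f"ct_{iz:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_ct_series(directory: str | Path) -> CTStack:
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ParseError("no DICOM files in directory")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        if getattr(ds, "Modality", "") != "CT":
            continue
        z = float(ds.ImagePositionPatient[2])
        hu = ds.pixel_array.astype(np.int16)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        if slope != 1.0 or inter != 0.0:
            hu = (hu * slope + inter).astype(np.int16)
        slices.append((z, hu, ds))
    if not slices:
        raise ParseError("no CT slices found")
    slices.sort(key=lambda s: s[0])
    zs = np.array([s[0] for s in slices])
    ds0 = slices[0][2]
    dz = float(zs[1] - zs[0]) if len(zs) > 1 else float(getattr(ds0, "SliceThickness", 1.0))
    spacing = np.array([float(ds0.PixelSpacing[1]), float(ds0.PixelSpacing[0]), dz])
    origin = np.array([
        float(ds0.ImagePositionPatient[0]), float(ds0.ImagePositionPatient[1]), zs[0]
    ])
    vol = np.stack([s[1] for s in slices])
    return CTStack(origin, spacing, vol)
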