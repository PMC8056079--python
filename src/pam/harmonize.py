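"""Volume IO and the harmonization protocol.

Every scan entering the pipeline is brought onto a standard grid:
isotropic linear resampling at 2 mm, clipping of Hounsfield units to
[-120, 300] (fat to cancellous bone), rescaling to [0, 1], and center
crop/zero-pad to 192x192x192 voxels (axial extent 160 for chest).
Resampling runs first so that interpolation happens in HU.
"""

from __future__ import annotations

import datetime as dt
import json
import os
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import (ANALYTES, HU_WINDOW, REGION_SHAPES, TARGET_SPACING_MM,
                    FormatError, InvalidMetadataError, PatientRecord,
                    VolumeGrid)

MAX_AXIAL_SPACING_MM = 5.0  # inclusion: "high-resolution" slices only


def resample_isotropic(volume: VolumeGrid,
                       target_spacing: float = TARGET_SPACING_MM) -> VolumeGrid:
    """Linearly resample onto an isotropic grid of ``target_spacing`` mm."""
    spacing = np.asarray(volume.spacing_mm, dtype=float)
    if np.any(spacing <= 0) or target_spacing <= 0:
        raise InvalidMetadataError("voxel spacing must be positive")
    zoom = spacing / float(target_spacing)
    if np.allclose(zoom, 1.0):
        return volume.with_intensities(volume.intensities.copy(),
                                       spacing_mm=(target_spacing,) * 3)
    # node-centered resampling: first and last sample positions map onto
    # each other exactly, so no boundary extrapolation is needed
    out = ndimage.zoom(volume.intensities.astype(np.float64), zoom,
                       order=1, mode="nearest", grid_mode=False,
                       prefilter=False)
    return volume.with_intensities(out, spacing_mm=(target_spacing,) * 3)


def clip_rescale(volume: VolumeGrid, window: tuple = HU_WINDOW) -> VolumeGrid:
    """Clip HU to ``window`` and rescale linearly onto [0, 1].

    Already-normalized volumes pass through unchanged, making the
    operation idempotent across repeated harmonization.
    """
    if volume.intensity_units == "normalized":
        return volume.with_intensities(volume.intensities.copy())
    lo, hi = window
    out = (np.clip(volume.intensities.astype(np.float64), lo, hi) - lo) / (hi - lo)
    return volume.with_intensities(out, intensity_units="normalized")


def crop_pad(volume: VolumeGrid, target_shape: tuple) -> VolumeGrid:
    """Center crop where larger, symmetric zero-pad where smaller."""
    arr = volume.intensities
    for axis, target in enumerate(target_shape):
        size = arr.shape[axis]
        if size > target:
            start = (size - target) // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(start, start + target)
            arr = arr[tuple(sl)]
        elif size < target:
            before = (target - size) // 2
            pad = [(0, 0)] * 3
            pad[axis] = (before, target - size - before)
            arr = np.pad(arr, pad)
    return volume.with_intensities(arr)


def harmonize(volume: VolumeGrid, region: str = None,
              target_spacing: float = TARGET_SPACING_MM,
              region_shapes: dict = None) -> VolumeGrid:
    """Full protocol: resample -> clip -> rescale -> crop/pad."""
    shapes = region_shapes or REGION_SHAPES
    region = region or volume.body_region
    if region not in shapes:
        region = "whole"
    out = resample_isotropic(volume, target_spacing)
    out = clip_rescale(out)
    out = crop_pad(out, shapes[region])
    out.body_region = region if region in ("chest", "abdomen") else out.body_region
    return out


# ---------------------------------------------------------------------------
# Volume IO
# ---------------------------------------------------------------------------

def load_volume(path, format: str = None) -> VolumeGrid:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Intensities come back in HU, axial axis first, slice order normalized
    head to toe. Series failing the acquisition requirements (non-axial,
    missing slices, axial spacing > 5 mm) raise :class:`FormatError`.
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: Path) -> VolumeGrid:
    import nibabel as nib

    img = nib.load(str(path))
    try:
        nib.orientations.aff2axcodes(img.affine)
        canonical = nib.as_closest_canonical(img)
        orientation_known = True
    except Exception:
        canonical = img
        orientation_known = False
    data = np.asanyarray(canonical.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError("expected a 3-D NIfTI volume")
    zooms = canonical.header.get_zooms()[:3]
    # canonical = RAS; flip S->I so index 0 is the most superior slice
    arr = np.flip(data.transpose(2, 1, 0), 0).copy()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if spacing[0] > MAX_AXIAL_SPACING_MM:
        raise FormatError(
            f"axial spacing {spacing[0]:.1f} mm exceeds "
            f"{MAX_AXIAL_SPACING_MM:.0f} mm inclusion limit")
    origin = tuple(float(v) for v in canonical.affine[:3, 3])
    return VolumeGrid(arr, spacing_mm=spacing, origin_mm=origin,
                      axial_axis=0, intensity_units="HU",
                      orientation_known=orientation_known)


def _load_dicom_series(path: Path) -> VolumeGrid:
    import pydicom

    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".dcm", "") and p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM slices found under {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise FormatError("mixed DICOM series in one directory")
    for ds in slices:
        iop = np.asarray(getattr(ds, "ImageOrientationPatient",
                                 [1, 0, 0, 0, 1, 0]), dtype=float)
        if not (np.allclose(iop[:3], [1, 0, 0], atol=0.01)
                and np.allclose(iop[3:], [0, 1, 0], atol=0.01)):
            raise FormatError("non-axial acquisition")
    # patient z increases toward the head: sort descending = head to toe
    slices.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    gaps = np.abs(np.diff(zs))
    if len(gaps) == 0:
        raise FormatError("series has a single slice")
    if np.ptp(gaps) > 0.01 * gaps.mean():
        raise FormatError("non-uniform slice spacing (missing slices?)")
    axial_spacing = float(gaps.mean())
    if axial_spacing > MAX_AXIAL_SPACING_MM:
        raise FormatError(
            f"slice spacing {axial_spacing:.1f} mm exceeds "
            f"{MAX_AXIAL_SPACING_MM:.0f} mm inclusion limit")
    first = slices[0]
    px = [float(v) for v in first.PixelSpacing]
    arr = np.stack([
        ds.pixel_array.astype(np.float64) * float(getattr(ds, "RescaleSlope", 1.0))
        + float(getattr(ds, "RescaleIntercept", 0.0))
        for ds in slices])
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return VolumeGrid(arr, spacing_mm=(axial_spacing, px[0], px[1]),
                      origin_mm=origin, axial_axis=0, intensity_units="HU")


def save_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI (RAS), inverse of :func:`_load_nifti`."""
    import nibabel as nib

    arr = np.flip(volume.intensities, 0).transpose(2, 1, 0)
    sp = volume.spacing_mm
    affine = np.diag([sp[2], sp[1], sp[0], 1.0])
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr), affine), str(path))


def save_provenance(volume: VolumeGrid, source: str, out_path) -> None:
    sidecar = {
        "source": str(source),
        "spacing_mm": list(volume.spacing_mm),
        "shape": list(volume.shape),
        "body_region": volume.body_region,
        "intensity_units": volume.intensity_units,
        "transform": "resample->clip->rescale->crop_pad",
    }
    with open(out_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value)[:10])


def read_clinical_tables(patients_csv, blood_csv=None,
                         lesions_csv=None) -> dict:
    """Read clinical CSVs into :class:`PatientRecord` objects.

    ``patients_csv`` columns: patient_id, treatment_start, event_date,
    deceased, age. ``blood_csv``: patient_id, date, analyte, value.
    ``lesions_csv``: patient_id, date, volume_mm3.
    """
    import pandas as pd

    patients = pd.read_csv(patients_csv, dtype={"patient_id": str})
    records = {}
    for _, row in patients.iterrows():
        records[row["patient_id"]] = PatientRecord(
            patient_id=row["patient_id"],
            treatment_start=_parse_date(row["treatment_start"]),
            death_or_censor=_parse_date(row["event_date"]),
            deceased=bool(row["deceased"]),
            age_years=float(row.get("age", float("nan"))),
        )
    if blood_csv is not None and os.path.exists(str(blood_csv)):
        blood = pd.read_csv(blood_csv, dtype={"patient_id": str})
        for _, row in blood.iterrows():
            if row["analyte"] not in ANALYTES:
                raise ValueError(f"unknown analyte {row['analyte']!r}")
            rec = records.get(row["patient_id"])
            if rec is not None:
                rec.blood_values.append(
                    (_parse_date(row["date"]), row["analyte"],
                     float(row["value"])))
    if lesions_csv is not None and os.path.exists(str(lesions_csv)):
        lesions = pd.read_csv(lesions_csv, dtype={"patient_id": str})
        for _, row in lesions.iterrows():
            rec = records.get(row["patient_id"])
            if rec is not None:
                if rec.lesion_volumes is None:
                    rec.lesion_volumes = []
                rec.lesion_volumes.append(
                    (_parse_date(row["date"]), float(row["volume_mm3"])))
    return records
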