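"""Core data containers exchanged between pipeline stages."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

BODY_REGIONS = ("whole", "chest", "abdomen", "unknown")
ANALYTES = ("hemoglobin", "leukocyte", "thrombocyte", "erythrocyte")

#: harmonized voxel spacing (mm, isotropic)
TARGET_SPACING_MM = 2.0
#: Hounsfield clipping window: fat to cancellous bone
HU_WINDOW = (-120.0, 300.0)
#: harmonized grid shapes, axial axis first
REGION_SHAPES = {
    "whole": (192, 192, 192),
    "abdomen": (192, 192, 192),
    "chest": (160, 192, 192),
}


class InvalidMetadataError(ValueError):
    """Volume metadata (spacing, orientation) is unusable."""


class FormatError(ValueError):
    """Input files violate the acquisition requirements."""


@dataclass
class VolumeGrid:
    """A 3-D intensity volume with geometry metadata.

    ``intensities`` is indexed (axial, coronal-row, sagittal-col) with the
    axial axis running head to toe (index 0 = most superior slice).
    ``intensity_units`` is "HU" for raw Hounsfield data and "normalized"
    once intensities have been clipped and rescaled to [0, 1].
    """

    intensities: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    origin_mm: tuple = (0.0, 0.0, 0.0)
    axial_axis: int = 0
    body_region: str = "unknown"
    intensity_units: str = "HU"
    orientation_known: bool = True

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise InvalidMetadataError("volume must be 3-D")
        if not 0 <= self.axial_axis < 3:
            raise InvalidMetadataError("axial_axis out of range")
        if self.body_region not in BODY_REGIONS:
            raise InvalidMetadataError(f"unknown body_region {self.body_region!r}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(s) for s in self.origin_mm)

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[self.axial_axis]

    def axial_slice(self, index: int) -> np.ndarray:
        return np.take(self.intensities, index, axis=self.axial_axis)

    def with_intensities(self, intensities: np.ndarray, **updates) -> "VolumeGrid":
        return replace(self, intensities=intensities, **updates)


@dataclass
class ScanRecord:
    """One scan of one patient: acquisition date plus the volume."""

    date: dt.date
    volume: VolumeGrid
    region: str = "unknown"


@dataclass
class PatientRecord:
    """Clinical follow-up record for one patient."""

    patient_id: str
    treatment_start: dt.date
    death_or_censor: dt.date
    deceased: bool
    age_years: float = float("nan")
    scans: list = field(default_factory=list)
    blood_values: list = field(default_factory=list)  # (date, analyte, value)
    lesion_volumes: Optional[list] = None  # (date, volume mm^3)

    def __post_init__(self):
        if self.scans:
            first = min(s.date for s in self.scans)
            if self.death_or_censor < first:
                raise ValueError("death/censor date precedes earliest scan")

    @property
    def numeric_id(self) -> int:
        digits = "".join(c for c in self.patient_id if c.isdigit())
        if not digits:
            raise ValueError(f"patient_id {self.patient_id!r} has no digits")
        return int(digits)

    def scans_of_region(self, region: str) -> list:
        out = [s for s in self.scans if s.region == region]
        dates = [s.date for s in out]
        if len(set(dates)) != len(dates):
            raise ValueError("duplicate scan dates within one region")
        return sorted(out, key=lambda s: s.date)


@dataclass
class AffineTransform:
    """12-parameter affine map in voxel coordinates about the volume center."""

    linear: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,), voxels

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation,
                                      dtype=np.float64).reshape(3)
        if not (np.isfinite(self.linear).all()
                and np.isfinite(self.translation).all()):
            raise ValueError("affine parameters must be finite")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(cls, params) -> "AffineTransform":
        params = np.asarray(params, dtype=np.float64).reshape(12)
        return cls(params[:9].reshape(3, 3), params[9:])

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.linear.reshape(9), self.translation])

    def coordinate_map(self, point: np.ndarray, center: np.ndarray) -> np.ndarray:
        """T(x) = A (x - c) + c + t, the sampling location for voxel x."""
        return (self.linear @ (point - center)) + center + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform equivalent to applying ``self`` to the image first,
        then ``other`` (coordinate map x -> T_self(T_other(x)))."""
        return AffineTransform(self.linear @ other.linear,
                               self.linear @ other.translation
                               + self.translation)


@dataclass
class DisplacementField:
    """Per-voxel displacement (voxel units) on the fixed-image grid."""

    vectors: np.ndarray  # (3, D, H, W)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError("field must have shape (3, D, H, W)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("field must be finite")

    @property
    def spatial_shape(self) -> tuple:
        return self.vectors.shape[1:]


@dataclass
class ScanPair:
    """Ordered (prior, subsequent) scans of one patient."""

    patient_id: str
    prior: VolumeGrid
    subsequent: VolumeGrid
    prior_date: dt.date
    subsequent_date: dt.date
    days_from_treatment_start: int
    days_between_scans: int
    region: str = "unknown"

    def __post_init__(self):
        if not (0 < self.days_between_scans <= 365):
            raise ValueError("days_between_scans must be in (0, 365]")


@dataclass
class SurvivalLabel:
    positive: bool
    evaluable: bool


@dataclass
class LatentFeatureVector:
    """96 pooled tracker features plus the two temporal covariates."""

    features: np.ndarray  # (96,)
    t_start: float  # days from treatment start to the subsequent scan
    t_delta: float  # days between the two scans

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64).reshape(-1)
        if self.features.shape != (96,):
            raise ValueError("expected exactly 96 latent features")

    def as_row(self) -> np.ndarray:
        return np.concatenate([self.features, [self.t_start, self.t_delta]])
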