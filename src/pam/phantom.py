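"""Seeded pseudo-CT phantoms with machine-readable ground truth.

The generator emulates the features the pipeline relies on, at desk
scale: a monotone head-to-toe anatomical gradient (so slice ordering is
learnable), an elliptical body outline, organ-like blobs, growing or
shrinking lesions, follow-up pairs related by known affine + smooth
deformable warps, and cohorts whose survival hazard depends on each
patient's lesion growth rate. All intensities live in [0, 1] on the
harmonized scale; every fixture carries its ground truth alongside.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .grids import (AffineTransform, PatientRecord, ScanPair, ScanRecord,
                    VolumeGrid)

#: landmark planes as anatomical fractions of the head-to-toe extent
LANDMARK_FRACTIONS = {
    "lower_neck": 0.12,
    "upper_diaphragm": 0.42,
    "lower_diaphragm": 0.50,
    "lower_pelvis": 0.92,
}


@dataclass
class PhantomSpec:
    shape: tuple = (64, 32, 32)
    seed: int = 0
    landmark_planes: dict = None  # name -> axial index
    organ_blobs: list = field(default_factory=list)  # (center, radius, intensity)
    lesions: list = field(default_factory=list)  # (center, radius0, growth/day)
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.landmark_planes is None:
            n = self.shape[0]
            self.landmark_planes = {
                k: int(round(f * (n - 1)))
                for k, f in LANDMARK_FRACTIONS.items()}
        planes = [self.landmark_planes[k] for k in
                  ("lower_neck", "upper_diaphragm", "lower_diaphragm",
                   "lower_pelvis") if k in self.landmark_planes]
        if planes != sorted(planes) or len(set(planes)) != len(planes):
            raise ValueError("landmark planes must strictly increase "
                             "head-to-toe")

    def ground_truth(self) -> dict:
        return {
            "shape": list(self.shape),
            "seed": self.seed,
            "landmark_planes": dict(self.landmark_planes),
            "lesions": [[list(c), float(r), float(g)]
                        for c, r, g in self.lesions],
        }


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def make_phantom(spec: PhantomSpec, lesion_age_days: float = 0.0) -> VolumeGrid:
    """Render a phantom volume; deterministic given ``spec.seed``.

    ``lesion_age_days`` advances each lesion radius by its growth rate,
    so follow-up scans of the same anatomy share one spec.
    """
    d, h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    u = np.linspace(0.0, 1.0, d)[:, None, None]  # anatomical fraction

    # body outline: elliptical cylinder, radius varying smoothly with u
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry = (0.30 + 0.12 * np.sin(np.pi * u)) * h
    rx = (0.33 + 0.10 * np.sin(np.pi * u + 0.4)) * w
    body = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0

    # head-to-toe gradient plus a few fixed internal bands per fraction
    base = 0.20 + 0.45 * u + 0.12 * np.sin(6.0 * np.pi * u)
    vol = np.where(body, base * np.ones((d, h, w)), 0.05)

    for center, radius, intensity in spec.organ_blobs:
        center = np.asarray(center, dtype=float)
        if np.any(center < 0) or np.any(center >= np.asarray(spec.shape)):
            raise ValueError(f"organ blob center {center} outside extent")
        vol[_sphere_mask(spec.shape, center, radius)] = intensity

    for center, radius0, growth in spec.lesions:
        center = np.asarray(center, dtype=float)
        if np.any(center < 0) or np.any(center >= np.asarray(spec.shape)):
            raise ValueError(f"lesion center {center} outside extent")
        radius = max(radius0 + growth * lesion_age_days, 0.0)
        if radius > 0:
            vol[_sphere_mask(spec.shape, center, radius)] = 0.95

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return VolumeGrid(np.clip(vol, 0.0, 1.0),
                      spacing_mm=(2.0, 2.0, 2.0), axial_axis=0,
                      body_region="whole", intensity_units="normalized")


def write_ground_truth(spec: PhantomSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec.ground_truth(), fh, indent=2)


# ---------------------------------------------------------------------------
# Warped follow-up pairs
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Smooth random displacement field: gaussian-filtered white noise
    rescaled to a maximum amplitude (voxels)."""

    amplitude: float = 2.0
    smoothness: float = 6.0  # gaussian sigma in voxels
    seed: int = 0

    def __post_init__(self):
        if self.smoothness < 2.0:
            raise ValueError("field smoothness scale must be >= 2 voxels")


def smooth_random_field(shape, spec: FieldSpec) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    field = rng.normal(size=(3,) + tuple(shape))
    field = np.stack([gaussian_filter(f, spec.smoothness) for f in field])
    peak = np.abs(field).max()
    if peak > 0:
        field *= spec.amplitude / peak
    return field


def total_flow(affine: AffineTransform, deform: np.ndarray) -> np.ndarray:
    """Flow u(x) with subsequent(x) = prior(x + u(x)), composing the
    affine coordinate map (about the volume center) with a deformation."""
    shape = deform.shape[1:]
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij")).astype(np.float64)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    pts = base.reshape(3, -1).T
    mapped = (pts - center) @ affine.linear.T + center + affine.translation
    return (mapped.T.reshape(deform.shape) - base) + deform


def make_warped_pair(spec: PhantomSpec,
                     affine: AffineTransform = None,
                     field_spec: FieldSpec = None,
                     lesion_delta_days: float = 0.0,
                     days_between: int = 60) -> tuple:
    """Build a (prior, subsequent) pair with known ground-truth warp.

    subsequent(x) = prior_grown(x + u_gt(x)) where prior_grown is the
    phantom with lesions advanced by ``lesion_delta_days`` and u_gt
    composes the affine with a smooth random deformation. Returns
    (ScanPair, truth dict) where truth carries the flow, the landmark
    planes and their correspondences.
    """
    affine = affine or AffineTransform.identity()
    prior = make_phantom(spec)
    grown = make_phantom(spec, lesion_age_days=lesion_delta_days)
    deform = (smooth_random_field(spec.shape, field_spec)
              if field_spec is not None
              else np.zeros((3,) + tuple(spec.shape)))
    flow = total_flow(affine, deform)
    extent = min(spec.shape)
    if np.abs(flow).max() > extent / 4.0:
        raise ValueError("ground-truth displacement exceeds 1/4 extent; "
                         "fixture unusable")
    subsequent_arr = Tensor(grown.intensities[None, None]).warp3d(
        Tensor(flow[None])).data[0, 0]
    subsequent = prior.with_intensities(subsequent_arr)

    landmarks = {}
    for name, z in spec.landmark_planes.items():
        p = np.array([z, (spec.shape[1] - 1) / 2.0,
                      (spec.shape[2] - 1) / 2.0])
        idx = tuple(np.clip(np.round(p).astype(int), 0,
                            np.asarray(spec.shape) - 1))
        landmarks[name] = {
            "fixed_point": p.tolist(),
            "moving_point": (p + flow[(slice(None),) + idx]).tolist(),
        }
    pair = ScanPair(patient_id="phantom", prior=prior, subsequent=subsequent,
                    prior_date=dt.date(2000, 1, 1),
                    subsequent_date=dt.date(2000, 1, 1)
                    + dt.timedelta(days=days_between),
                    days_from_treatment_start=days_between,
                    days_between_scans=days_between,
                    region=prior.body_region)
    truth = {"flow": flow, "affine_params": affine.params.tolist(),
             "landmarks": landmarks,
             "lesion_delta_days": lesion_delta_days}
    return pair, truth


# ---------------------------------------------------------------------------
# Cohorts with survival tied to lesion growth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    n_patients: int = 40
    scans_min: int = 3
    scans_max: int = 4
    scan_interval_days: float = 75.0
    baseline_hazard: float = 1.0 / 400.0  # per day
    log_hazard_per_sd: float = 1.5
    censor_horizon_days: int = 730
    growth_rate_sd: float = 0.02  # lesion radius voxels/day
    shape: tuple = (64, 32, 32)
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0 or self.censor_horizon_days <= 0:
            raise ValueError("rates and horizon must be positive")


def make_cohort(spec: SyntheticCohortSpec) -> tuple:
    """Simulate a follow-up cohort: per-patient phantom series whose
    lesions grow at a patient-specific rate, and exponential survival
    with log-hazard proportional to the standardized growth rate.

    Returns (records, truth): records is a dict patient_id ->
    PatientRecord with volumes attached; truth carries the growth
    rates, hazards and raw event times. Patient IDs are zero-padded
    integers so the even/odd discovery split is exercisable.
    """
    rng = np.random.default_rng(spec.seed)
    records, truth = {}, {"patients": {}}
    treatment_start = dt.date(2015, 6, 1)
    for i in range(spec.n_patients):
        pid = f"{i:03d}"
        growth = rng.normal(0.0, spec.growth_rate_sd)
        z = growth / spec.growth_rate_sd
        hazard = spec.baseline_hazard * np.exp(spec.log_hazard_per_sd * z)
        time_to_death = rng.exponential(1.0 / hazard)
        deceased = time_to_death <= spec.censor_horizon_days
        event_days = int(min(np.ceil(time_to_death),
                             spec.censor_horizon_days))

        n_scans = int(rng.integers(spec.scans_min, spec.scans_max + 1))
        first = int(rng.integers(-30, 10))
        scan_days = [first]
        for _ in range(n_scans - 1):
            scan_days.append(scan_days[-1] + int(
                rng.normal(spec.scan_interval_days,
                           spec.scan_interval_days / 6.0)))
        scan_days = [min(s, event_days - 1) for s in scan_days]
        scan_days = sorted(set(scan_days))

        d, h, w = spec.shape
        z_lo = min(int(0.50 * d) + 4, d - 2)
        z_hi = max(min(int(0.9 * d) - 4, d - 1), z_lo + 1)
        lesion_center = (int(rng.integers(z_lo, z_hi)),
                         int(rng.integers(h // 4, 3 * h // 4)),
                         int(rng.integers(w // 4, 3 * w // 4)))
        pspec = PhantomSpec(
            shape=spec.shape, seed=int(rng.integers(2 ** 31)),
            lesions=[(lesion_center, 2.5, growth)],
            organ_blobs=[((min(int(0.65 * d), d - 1), h // 2 - h // 5,
                           w // 2), h / 6.0, 0.55)],
        )
        scans = []
        for day in scan_days:
            vol = make_phantom(pspec, lesion_age_days=float(day - scan_days[0]))
            scans.append(ScanRecord(date=treatment_start
                                    + dt.timedelta(days=int(day)),
                                    volume=vol, region="whole"))
        records[pid] = PatientRecord(
            patient_id=pid,
            treatment_start=treatment_start,
            death_or_censor=treatment_start + dt.timedelta(days=event_days),
            deceased=bool(deceased),
            age_years=float(rng.normal(65.0, 8.0)),
            scans=scans,
        )
        truth["patients"][pid] = {
            "growth_rate": float(growth),
            "hazard_per_day": float(hazard),
            "time_to_death_days": float(time_to_death),
            "deceased": bool(deceased),
            "scan_days": [int(s) for s in scan_days],
            "lesion_center": list(lesion_center),
            "phantom_seed": pspec.seed,
        }
    return records, truth
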