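"""Anatomical localization by self-supervised slice ordering.

A 2-D convnet is trained, siamese-style, to decide which of two axial
slices from the same scan lies closer to the head. Solving this forces
the network to assign each anatomy a score that increases head to toe.
A robust (RANSAC) line then maps scores to axial coordinates, so a
landmark calibrated once by its score (e.g. the top of the diaphragm
around score 25 in the original formulation) can be located in any scan
by inverting the line. Chest and abdomen are cropped between the
located landmark planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor
from .grids import REGION_SHAPES, VolumeGrid
from .harmonize import crop_pad
from .networks import SliceScorer2d, load_model, save_model

LANDMARK_NAMES = ("lower_neck", "upper_diaphragm", "lower_diaphragm",
                  "lower_pelvis")
#: calibrated score anchor for the upper diaphragm
DIAPHRAGM_TARGET_SCORE = 25.0


class FitFailureError(RuntimeError):
    """Robust score-to-coordinate fit could not be produced."""


@dataclass
class SlicePairSample:
    slice_a: np.ndarray
    slice_b: np.ndarray
    z_a: int
    z_b: int

    def __post_init__(self):
        if self.z_a == self.z_b:
            raise ValueError("slice pair must have distinct axial coordinates")

    @property
    def label(self) -> int:
        """1 when slice_a is superior (closer to the head)."""
        return int(self.z_a < self.z_b)


@dataclass
class AnatomicalScoreMap:
    scores: np.ndarray
    fit_slope: float = float("nan")
    fit_intercept: float = float("nan")
    inlier_mask: np.ndarray = None

    @property
    def n_slices(self) -> int:
        return len(self.scores)

    @property
    def inlier_fraction(self) -> float:
        if self.inlier_mask is None:
            return float("nan")
        return float(np.mean(self.inlier_mask))


@dataclass
class LandmarkSpec:
    name: str
    target_score: float


@dataclass
class LocalizerConfig:
    """Training configuration. Defaults follow the full-scale recipe
    (Adam, lr 1e-3, batch of 8 scans with one slice pair each, 50,000
    iterations); tests override ``iterations`` for desk-scale runs."""

    iterations: int = 50_000
    learning_rate: float = 1e-3
    batch_scans: int = 8
    seed: int = 0
    widths: tuple = (8, 16, 32)
    holdout_fraction: float = 0.2
    ransac_seed: int = 0
    residual_threshold_factor: float = 2.0
    landmark_targets: dict = field(default_factory=dict)


@dataclass
class LocalizerModel:
    scorer: SliceScorer2d
    config: LocalizerConfig
    holdout_accuracy: float = float("nan")

    def save(self, path) -> None:
        cfg = self.scorer.config()
        cfg["holdout_accuracy"] = self.holdout_accuracy
        save_model(path, cfg, self.scorer.parameters())

    @classmethod
    def load(cls, path, config: LocalizerConfig = None) -> "LocalizerModel":
        model = load_model(path, {
            "slice_scorer": lambda c: SliceScorer2d(widths=c["widths"],
                                                    seed=c["seed"])})
        return cls(scorer=model, config=config or LocalizerConfig())


def sample_slice_pair(volume: VolumeGrid,
                      rng: np.random.Generator) -> SlicePairSample:
    n = volume.n_slices
    z_a, z_b = rng.choice(n, size=2, replace=False)
    return SlicePairSample(volume.axial_slice(int(z_a)),
                           volume.axial_slice(int(z_b)), int(z_a), int(z_b))


def sample_training_batch(scans, config: "LocalizerConfig",
                          rng: np.random.Generator) -> tuple:
    """One training batch: ``batch_scans`` random scans, one random
    slice pair per scan. Returns (slice stack (2B, H, W), labels (B,))
    with pair slices interleaved (a0, b0, a1, b1, ...)."""
    batch, labels = [], []
    for _ in range(config.batch_scans):
        vol = scans[rng.integers(len(scans))]
        pair = sample_slice_pair(vol, rng)
        batch.append(pair.slice_a)
        batch.append(pair.slice_b)
        labels.append(pair.label)
    return np.stack(batch), np.asarray(labels, dtype=np.float64)


def _ordering_accuracy(model: SliceScorer2d, scans, rng, n_pairs=200) -> float:
    correct = 0
    for _ in range(n_pairs):
        vol = scans[rng.integers(len(scans))]
        pair = sample_slice_pair(vol, rng)
        s = model.score_array(np.stack([pair.slice_a, pair.slice_b]))
        predicted = int(s[0] < s[1])  # superior slice has the lower score
        correct += int(predicted == pair.label)
    return correct / n_pairs


def train_localizer(scans, config: LocalizerConfig = None) -> LocalizerModel:
    """Train the slice-ordering scorer on a corpus of harmonized scans.

    Each iteration draws ``batch_scans`` random scans and one random
    slice pair per scan; binary cross-entropy on sigmoid(s_b - s_a)
    against the "a is superior" label makes the score increase head to
    toe.
    """
    config = config or LocalizerConfig()
    scans = list(scans)
    if not scans:
        raise ValueError("empty scan corpus")
    if any(v.n_slices < 2 for v in scans):
        raise ValueError("every scan needs at least 2 slices")
    rng = np.random.default_rng(config.seed)
    n_hold = int(round(config.holdout_fraction * len(scans)))
    order = rng.permutation(len(scans))
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    train_scans = [scans[i] for i in train_idx] or scans
    hold_scans = [scans[i] for i in hold_idx] or scans

    model = SliceScorer2d(widths=config.widths, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    eps = 1e-7
    for _ in range(config.iterations):
        batch, y = sample_training_batch(train_scans, config, rng)
        scores = model(Tensor(batch[:, None]))
        s_a, s_b = scores[0::2], scores[1::2]
        p = (s_b - s_a).sigmoid()
        loss = -(Tensor(y) * (p + eps).log()
                 + Tensor(1.0 - y) * (1.0 - p + eps).log()).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()

    acc = _ordering_accuracy(model, hold_scans,
                             np.random.default_rng(config.seed + 1))
    return LocalizerModel(scorer=model, config=config, holdout_accuracy=acc)


def score_slices(model: LocalizerModel, volume: VolumeGrid) -> AnatomicalScoreMap:
    """One anatomical score per axial slice (head-to-toe order)."""
    slices = np.stack([volume.axial_slice(i) for i in range(volume.n_slices)])
    return AnatomicalScoreMap(scores=model.scorer.score_array(slices))


def fit_score_line(score_map: AnatomicalScoreMap,
                   config: LocalizerConfig = None) -> AnatomicalScoreMap:
    """Robust linear fit score ~ slope * z + intercept via RANSAC.

    The residual threshold defaults to twice the median absolute
    residual of an initial least-squares fit; exact linear data
    short-circuits to the least-squares solution.
    """
    config = config or LocalizerConfig()
    s = np.asarray(score_map.scores, dtype=np.float64)
    if s.size < 8:
        raise FitFailureError("need at least 8 slices for a robust fit")
    if np.allclose(s, s[0]):
        raise FitFailureError("constant scores: no score-coordinate relation")
    z = np.arange(s.size, dtype=np.float64)
    slope0, intercept0 = np.polyfit(z, s, 1)
    resid = np.abs(s - (slope0 * z + intercept0))
    mad = np.median(resid)
    if mad < 1e-12:  # noiseless line: least squares is already exact
        score_map.fit_slope = float(slope0)
        score_map.fit_intercept = float(intercept0)
        score_map.inlier_mask = np.ones(s.size, dtype=bool)
        return score_map
    from sklearn.linear_model import LinearRegression, RANSACRegressor

    ransac = RANSACRegressor(
        estimator=LinearRegression(),
        residual_threshold=config.residual_threshold_factor * mad,
        random_state=config.ransac_seed,
    )
    try:
        ransac.fit(z[:, None], s)
    except ValueError as exc:
        raise FitFailureError(str(exc)) from exc
    score_map.fit_slope = float(ransac.estimator_.coef_[0])
    score_map.fit_intercept = float(ransac.estimator_.intercept_)
    score_map.inlier_mask = ransac.inlier_mask_.copy()
    return score_map


def locate_landmark(score_map: AnatomicalScoreMap,
                    landmark: LandmarkSpec) -> int:
    """Invert the fitted line: z = (target - intercept) / slope."""
    if not np.isfinite(score_map.fit_slope) or score_map.fit_slope == 0:
        raise FitFailureError("score line has zero or unfit slope")
    z = (landmark.target_score - score_map.fit_intercept) / score_map.fit_slope
    return int(np.clip(np.round(z), 0, score_map.n_slices - 1))


def calibrate_landmarks(model: LocalizerModel, scans_with_planes,
                        config: LocalizerConfig = None) -> dict:
    """Calibrate landmark target scores on annotated fixtures.

    ``scans_with_planes`` yields (VolumeGrid, {landmark_name: z}); the
    target score of a landmark is the fitted-line value at its plane,
    averaged over scans.
    """
    config = config or LocalizerConfig()
    targets = {name: [] for name in LANDMARK_NAMES}
    for volume, planes in scans_with_planes:
        smap = fit_score_line(score_slices(model, volume), config)
        for name, z in planes.items():
            targets[name].append(smap.fit_slope * z + smap.fit_intercept)
    out = {name: float(np.mean(vals))
           for name, vals in targets.items() if vals}
    order = [out[n] for n in LANDMARK_NAMES if n in out]
    if order != sorted(order):
        warnings.warn("calibrated landmark scores are not monotone "
                      "head-to-toe; check the fixtures")
    return out


@dataclass
class RegionCrop:
    volume: VolumeGrid = None
    reason: str = ""

    @property
    def present(self) -> bool:
        return self.volume is not None


def crop_regions(volume: VolumeGrid, score_map: AnatomicalScoreMap,
                 landmark_targets: dict,
                 region_shapes: dict = None) -> tuple:
    """Crop chest (lower neck .. lower diaphragm) and abdomen (upper
    diaphragm .. lower pelvis) subvolumes, then pad to the region grid.
    The two spans overlap by the diaphragm slab by construction."""
    shapes = region_shapes or REGION_SHAPES
    z = {}
    for name in LANDMARK_NAMES:
        if name not in landmark_targets:
            raise ValueError(f"missing calibrated target for {name}")
        raw = (landmark_targets[name] - score_map.fit_intercept) \
            / score_map.fit_slope
        z[name] = raw  # unclamped, to detect absent regions
    order = [z[n] for n in LANDMARK_NAMES]
    if order != sorted(order):
        raise FitFailureError("landmark order inverted: inconsistent fit")

    def crop(z_top: float, z_bottom: float, region: str) -> RegionCrop:
        n = volume.n_slices
        span = z_bottom - z_top
        overlap = min(z_bottom, n - 1) - max(z_top, 0)
        if z_bottom < 0 or z_top > n - 1 or (span > 0
                                             and overlap < 0.5 * span):
            return RegionCrop(reason=f"{region} region (mostly) outside "
                                     "scan extent")
        a = int(np.clip(np.round(z_top), 0, n - 1))
        b = int(np.clip(np.round(z_bottom), 0, n - 1))
        if b - a < 2:
            return RegionCrop(reason=f"{region} span too short")
        sub = volume.intensities[a:b + 1]
        out = VolumeGrid(sub, spacing_mm=volume.spacing_mm,
                         origin_mm=volume.origin_mm,
                         body_region=region,
                         intensity_units=volume.intensity_units)
        return RegionCrop(volume=crop_pad(out, shapes[region]))

    chest = crop(z["lower_neck"], z["lower_diaphragm"], "chest")
    abdomen = crop(z["upper_diaphragm"], z["lower_pelvis"], "abdomen")
    return chest, abdomen
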