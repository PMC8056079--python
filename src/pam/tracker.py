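"""Two-stage registration tracker: affine pre-alignment + deformable field.

The moving image is the prior scan and the fixed image the subsequent
scan, so the estimated motion expresses change forward in time. An
affine network regresses 12 transform parameters from the stacked pair;
after warping, a U-Net regresses a dense displacement field (voxel
units on the harmonized grid). Training minimizes one minus the global
correlation coefficient between the warped moving and fixed images,
computed on curriculum-smoothed copies (box kernel 9, then 6, 3, and
none as epochs pass), plus three penalties: deviation of the linear
part from identity and the squared translation (each weighted 1/10),
and the mean squared forward-difference gradient of the field
(weighted 1/100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from ._autodiff import Adam, Tensor
from .grids import (AffineTransform, DisplacementField, ScanPair, VolumeGrid)
from .networks import (AffineNet3d, UNet3d, load_model, save_model,
                       IDENTITY_AFFINE_PARAMS)

AFFINE_PENALTY_WEIGHT = 0.1
DEFORMABLE_PENALTY_WEIGHT = 0.01


class UndefinedCorrelationWarning(UserWarning):
    pass


@dataclass
class CurriculumSchedule:
    """Box-smoothing kernel per epoch: starts at 9 and drops by 3 at
    each boundary epoch; no smoothing after the last boundary."""

    kernels: tuple = (9, 6, 3)
    boundaries: tuple = (100, 150, 175)

    def kernel_at(self, epoch: int) -> int:
        for k, b in zip(self.kernels, self.boundaries):
            if epoch < b:
                return k
        return 1  # identity

    def scaled(self, total_epochs: int,
               nominal_total: int = 200) -> "CurriculumSchedule":
        f = total_epochs / nominal_total
        return CurriculumSchedule(
            kernels=self.kernels,
            boundaries=tuple(int(round(b * f)) for b in self.boundaries))


def curriculum_smooth(volume, epoch: int,
                      schedule: CurriculumSchedule = None):
    """Smooth a volume according to the curriculum epoch."""
    schedule = schedule or CurriculumSchedule()
    k = schedule.kernel_at(epoch)
    if isinstance(volume, VolumeGrid):
        if k <= 1:
            return volume
        sm = Tensor(volume.intensities[None, None]).box_smooth(k).data[0, 0]
        return volume.with_intensities(sm)
    if isinstance(volume, Tensor):
        return volume.box_smooth(k)
    if k <= 1:
        return np.asarray(volume)
    arr = np.asarray(volume, dtype=np.float64)
    return Tensor(arr[None, None]).box_smooth(k).data[0, 0]


# ---------------------------------------------------------------------------
# Losses and penalties
# ---------------------------------------------------------------------------

def _as_flat_tensor(x):
    if isinstance(x, VolumeGrid):
        x = x.intensities
    if isinstance(x, Tensor):
        return x.reshape(-1), x.requires_grad
    return Tensor(np.asarray(x, dtype=np.float64).reshape(-1)), False


def correlation_loss(a, b, eps: float = 1e-12):
    """1 - global correlation coefficient; range [0, 2].

    Symmetric, and invariant to affine intensity rescaling of either
    argument. When both inputs are constant the correlation is
    undefined; the loss is then taken as 1 with a warning.
    """
    ta, grad_a = _as_flat_tensor(a)
    tb, grad_b = _as_flat_tensor(b)
    if ta.shape != tb.shape:
        raise ValueError("correlation_loss requires equal shapes")
    va = float(np.var(ta.data))
    vb = float(np.var(tb.data))
    if va < eps and vb < eps:
        warnings.warn("both volumes constant: correlation undefined, loss=1",
                      UndefinedCorrelationWarning)
        one = Tensor(1.0)
        return one if (grad_a or grad_b) else 1.0
    am = ta - ta.mean()
    bm = tb - tb.mean()
    cc = (am * bm).sum() * (((am ** 2.0).sum() * (bm ** 2.0).sum() + eps)
                            ** -0.5)
    loss = 1.0 - cc
    return loss if (grad_a or grad_b) else float(loss.data)


def _field_gradient_penalty_t(flow: Tensor) -> Tensor:
    """Mean squared forward-difference spatial gradient of a flow
    tensor (N, 3, D, H, W), averaged over all difference entries."""
    total = Tensor(0.0)
    count = 0
    for ax in (2, 3, 4):
        sl_hi = [slice(None)] * 5
        sl_lo = [slice(None)] * 5
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        d = flow[tuple(sl_hi)] - flow[tuple(sl_lo)]
        total = total + (d ** 2.0).sum()
        count += int(np.prod(d.shape))
    return total * (1.0 / count)


def _affine_penalty_t(params: Tensor, shape=None) -> Tensor:
    """||A - I||_F^2 + ||t_norm||^2 averaged over the batch.

    Inside the training objective the translation is expressed in
    half-extent units so that plausible multi-voxel shifts are not
    priced out by the 1/10 weight; the reporting metric
    :func:`regularization_penalties` keeps raw voxel units.
    """
    scale = np.ones(12)
    if shape is not None:
        scale[9:] = 2.0 / np.asarray(shape, dtype=np.float64)
    dev = (params - IDENTITY_AFFINE_PARAMS[None, :]) * scale[None, :]
    return (dev ** 2.0).sum() * (1.0 / params.shape[0])


def regularization_penalties(transform: AffineTransform,
                             field: DisplacementField,
                             affine_weight: float = AFFINE_PENALTY_WEIGHT,
                             deformable_weight: float = DEFORMABLE_PENALTY_WEIGHT,
                             ) -> float:
    """Weighted sum of the three penalties on a fitted transform/field."""
    a = np.sum((transform.linear - np.eye(3)) ** 2) \
        + np.sum(transform.translation ** 2)
    flow_t = Tensor(field.vectors[None])
    g = float(_field_gradient_penalty_t(flow_t).data)
    return affine_weight * a + deformable_weight * g


# ---------------------------------------------------------------------------
# Spatial transforms
# ---------------------------------------------------------------------------

def _param_scale(shape) -> np.ndarray:
    """Scale mapping raw network/optimizer outputs to affine parameters:
    linear deviations are used as-is, translations are expressed in
    half-extent units so all 12 parameters have comparable leverage."""
    scale = np.ones(12)
    scale[9:] = np.asarray(shape, dtype=np.float64) / 2.0
    return scale


def _params_from_raw(raw: Tensor, shape) -> Tensor:
    """params = identity + raw * scale, for raw (N, 12)."""
    return raw * _param_scale(shape)[None, :] + IDENTITY_AFFINE_PARAMS[None, :]


def _affine_flow_t(params: Tensor, shape: tuple) -> Tensor:
    """Flow tensor (N,3,D,H,W) realizing x -> A(x - c) + c + t, with c
    the volume center; linear in the 12 parameters."""
    d, h, w = shape
    base = np.stack(np.meshgrid(np.arange(d), np.arange(h), np.arange(w),
                                indexing="ij")).reshape(3, -1).T  # (V, 3)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    xc = base - center  # (V, 3)
    rows = []
    n = params.shape[0]
    for i in range(n):
        lin = params[i, :9].reshape(3, 3)
        trans = params[i, 9:].reshape(1, 3)
        flow = Tensor(xc) @ lin.transpose(1, 0) + trans - xc
        rows.append(flow.transpose(1, 0).reshape(1, 3, d, h, w))
    return Tensor.concat(rows, axis=0) if n > 1 else rows[0]


def apply_affine(volume: VolumeGrid, transform: AffineTransform) -> VolumeGrid:
    """Resample a volume through an affine map (trilinear, zero outside)."""
    params = Tensor(transform.params[None])
    flow = _affine_flow_t(params, volume.shape)
    out = Tensor(volume.intensities[None, None]).warp3d(flow)
    return volume.with_intensities(out.data[0, 0])


def warp(volume: VolumeGrid, field: DisplacementField) -> VolumeGrid:
    """Trilinear warp of a volume by a displacement field."""
    if field.spatial_shape != volume.shape:
        raise ValueError("field and volume shapes differ")
    out = Tensor(volume.intensities[None, None]).warp3d(
        Tensor(field.vectors[None]))
    return volume.with_intensities(out.data[0, 0])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TrackerConfig:
    steps: int = 200
    batch_size: int = 2
    learning_rate: float = 3e-4
    seed: int = 0
    affine_widths: tuple = (8, 16, 16, 32, 32)
    encoder_widths: tuple = (16, 32, 64, 96)
    schedule: CurriculumSchedule = dc_field(default_factory=CurriculumSchedule)
    schedule_nominal_epochs: int = 200
    affine_weight: float = AFFINE_PENALTY_WEIGHT
    deformable_weight: float = DEFORMABLE_PENALTY_WEIGHT
    holdout_id_multiple: int = 10
    val_every: int = 50


@dataclass
class TrackerOutput:
    affine: AffineTransform
    field: DisplacementField
    warped_moving: VolumeGrid
    latent_maps: np.ndarray  # (96, d, h, w)

    def __post_init__(self):
        if self.latent_maps.shape[0] != UNet3d.LATENT_CHANNELS:
            raise ValueError("latent maps must have 96 channels")


class TrackerModel:
    """Affine network + deformable U-Net for one body region."""

    version = 1

    def __init__(self, region: str = "abdomen",
                 config: TrackerConfig = None):
        self.region = region
        self.config = config or TrackerConfig()
        self.affine_net = AffineNet3d(widths=self.config.affine_widths,
                                      seed=self.config.seed)
        self.unet = UNet3d(enc_widths=self.config.encoder_widths,
                           seed=self.config.seed)
        self.loss_history: list = []
        self.val_history: list = []

    def parameters(self):
        return self.affine_net.parameters() + self.unet.parameters()

    def forward_t(self, moving: Tensor, fixed: Tensor):
        """Differentiable forward pass on (N,1,D,H,W) tensors."""
        if moving.shape != fixed.shape:
            raise ValueError("moving/fixed shape mismatch")
        down = 2 ** len(self.unet.enc_widths)
        if any(s % down for s in moving.shape[2:]):
            raise ValueError(f"volume dimensions {moving.shape[2:]} must be "
                             f"divisible by {down} (the encoder halves the "
                             "grid four times)")
        pair = Tensor.concat([moving, fixed], axis=1)
        params = _params_from_raw(self.affine_net(pair), moving.shape[2:])
        flow_aff = _affine_flow_t(params, moving.shape[2:])
        warped_aff = moving.warp3d(flow_aff)
        flow_def, latent = self.unet(
            Tensor.concat([warped_aff, fixed], axis=1))
        warped = warped_aff.warp3d(flow_def)
        return params, flow_def, warped, latent

    def track(self, pair: ScanPair) -> TrackerOutput:
        """Register prior (moving) onto subsequent (fixed)."""
        if pair.prior.shape != pair.subsequent.shape:
            raise ValueError("scan pair volumes differ in shape")
        moving = Tensor(pair.prior.intensities[None, None])
        fixed = Tensor(pair.subsequent.intensities[None, None])
        params, flow_def, warped, latent = self.forward_t(moving, fixed)
        return TrackerOutput(
            affine=AffineTransform.from_params(params.data[0]),
            field=DisplacementField(flow_def.data[0]),
            warped_moving=pair.subsequent.with_intensities(warped.data[0, 0]),
            latent_maps=latent.data[0],
        )

    def save(self, path) -> None:
        cfg = {"kind": "tracker", "version": self.version,
               "region": self.region,
               "affine_widths": list(self.config.affine_widths),
               "encoder_widths": list(self.config.encoder_widths),
               "seed": self.config.seed}
        save_model(path, cfg, self.parameters())

    @classmethod
    def load(cls, path) -> "TrackerModel":
        def build(cfg):
            config = TrackerConfig(affine_widths=tuple(cfg["affine_widths"]),
                                   encoder_widths=tuple(cfg["encoder_widths"]),
                                   seed=cfg["seed"])
            return cls(region=cfg["region"], config=config)

        return load_model(path, {"tracker": build})


def affine_forward(pair: ScanPair, model: TrackerModel) -> AffineTransform:
    """Run only the affine branch of the tracker."""
    if pair.prior.shape != pair.subsequent.shape:
        raise ValueError("scan pair volumes differ in shape")
    stacked = Tensor(np.stack([pair.prior.intensities,
                               pair.subsequent.intensities])[None])
    raw = model.affine_net(stacked)
    return AffineTransform.from_params(
        _params_from_raw(raw, pair.prior.shape).data[0])


def deformable_forward(warped_moving: VolumeGrid, fixed: VolumeGrid,
                       model: TrackerModel):
    """Run only the deformable branch; returns (field, latent maps)."""
    if warped_moving.shape != fixed.shape:
        raise ValueError("shape mismatch")
    stacked = Tensor(np.stack([warped_moving.intensities,
                               fixed.intensities])[None])
    flow, latent = model.unet(stacked)
    return DisplacementField(flow.data[0]), latent.data[0]


def _pair_tensors(pairs) -> tuple:
    moving = Tensor(np.stack([p.prior.intensities for p in pairs])[:, None])
    fixed = Tensor(np.stack([p.subsequent.intensities for p in pairs])[:, None])
    return moving, fixed


def _training_loss(model: TrackerModel, pairs, kernel: int,
                   config: TrackerConfig) -> Tensor:
    moving, fixed = _pair_tensors(pairs)
    params, flow_def, warped, _ = model.forward_t(moving, fixed)
    sim = correlation_loss(warped.box_smooth(kernel),
                           fixed.box_smooth(kernel))
    if not isinstance(sim, Tensor):
        sim = Tensor(sim)
    return (sim
            + config.affine_weight * _affine_penalty_t(params,
                                                       moving.shape[2:])
            + config.deformable_weight * _field_gradient_penalty_t(flow_def))


def _numeric_id(patient_id: str) -> int:
    digits = "".join(c for c in str(patient_id) if c.isdigit())
    return int(digits) if digits else 0


def train_tracker(pairs, config: TrackerConfig = None,
                  region: str = "abdomen") -> TrackerModel:
    """Train the tracker on a collection of scan pairs.

    Subjects whose numeric ID is a multiple of 10 are held out and
    monitored, never trained on. The curriculum schedule is rescaled to
    the configured number of steps (one step = one epoch unit).
    """
    config = config or TrackerConfig()
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 scan pairs")
    is_holdout = [_numeric_id(p.patient_id) % config.holdout_id_multiple == 0
                  for p in pairs]
    holdout = [p for p, h in zip(pairs, is_holdout) if h]
    train_pairs = [p for p, h in zip(pairs, is_holdout) if not h] or pairs

    model = TrackerModel(region=region, config=config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    schedule = config.schedule.scaled(config.steps,
                                      config.schedule_nominal_epochs)
    for step in range(config.steps):
        idx = rng.choice(len(train_pairs),
                         size=min(config.batch_size, len(train_pairs)),
                         replace=False)
        batch = [train_pairs[i] for i in idx]
        kernel = schedule.kernel_at(step)
        loss = _training_loss(model, batch, kernel, config)
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.loss_history.append(float(loss.data))
        if holdout and (step + 1) % config.val_every == 0:
            val = _training_loss(model, holdout[:config.batch_size],
                                 kernel, config)
            model.val_history.append((step, float(val.data)))
    return model


def recover_affine(moving: VolumeGrid, fixed: VolumeGrid,
                   steps: int = 300, learning_rate: float = 0.02,
                   seed: int = 0) -> AffineTransform:
    """Directly optimize the 12 affine parameters for one pair by
    gradient descent on the smoothed correlation loss (no network, no
    penalty terms: the oracle measures pure attainable alignment).

    Heavy smoothing early widens the capture range, then the kernel
    anneals away.
    """
    raw = Tensor(np.zeros((1, 12)), requires_grad=True)
    opt = Adam([raw], lr=learning_rate)
    mov = Tensor(moving.intensities[None, None])
    fix = Tensor(fixed.intensities[None, None])
    schedule = CurriculumSchedule().scaled(steps)
    for step in range(steps):
        kernel = schedule.kernel_at(step)
        params = _params_from_raw(raw, moving.shape)
        flow = _affine_flow_t(params, moving.shape)
        warped = mov.warp3d(flow)
        loss = correlation_loss(warped.box_smooth(kernel),
                                fix.box_smooth(kernel))
        opt.zero_grad()
        loss.backward()
        opt.step()
    return AffineTransform.from_params(
        _params_from_raw(raw, moving.shape).data[0])


def correspondences(affine: AffineTransform, field: DisplacementField,
                    points: np.ndarray) -> np.ndarray:
    """Map fixed-grid voxel locations to their predicted moving-image
    correspondences: p -> T_affine(p + u(p))."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    shape = field.spatial_shape
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    out = np.empty_like(points)
    for i, p in enumerate(points):
        idx = tuple(np.clip(np.round(p).astype(int), 0,
                            np.asarray(shape) - 1))
        u = field.vectors[(slice(None),) + idx]
        out[i] = affine.coordinate_map(p + u, center)
    return out


def make_cross_subject_pairs(volumes, n_pairs: int, seed: int = 0) -> list:
    """Random training pairs drawn across subjects (and within), the way
    the tracker is pre-trained: registering scans of (likely) different
    patients is a harder auxiliary task than follow-up matching.

    ``volumes``: list of (patient_id, VolumeGrid).
    """
    rng = np.random.default_rng(seed)
    import datetime as dt

    pairs = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(volumes), size=2, replace=False)
        pid_i, vol_i = volumes[i]
        _, vol_j = volumes[j]
        pairs.append(ScanPair(
            patient_id=str(pid_i),
            prior=vol_i, subsequent=vol_j,
            prior_date=dt.date(2000, 1, 1),
            subsequent_date=dt.date(2000, 1, 2),
            days_from_treatment_start=1, days_between_scans=1,
            region=vol_i.body_region))
    return pairs
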