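# Methods

This package implements a prognostic monitor for longitudinal
thoraco-abdominal CT in advanced-cancer follow-up: it quantifies
morphological change between successive scans of a patient with a
learned registration network and links those changes to 1-year overall
survival. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not
show.

## Harmonization

Every volume is brought onto a standard grid before any learning:

1. **Isotropic linear resampling** at 2 mm (node-centered: the first and
   last sample positions of the input and output grids coincide, so no
   boundary extrapolation occurs; round-tripping a band-limited volume
   through 2 → 4 → 2 mm stays within L∞ < 0.02 on the [0, 1] scale).
2. **HU clipping** to [−120, 300] (fat to cancellous bone) and linear
   rescaling to [0, 1]. Volumes carry an `intensity_units` tag; already
   normalized volumes pass through unchanged, which makes the operation
   idempotent across repeated harmonization.
3. **Center crop / symmetric zero-pad** to 192×192×192 voxels
   (192×192 with 160 axial slices for chest). No content-aware
   recentring is attempted.

Resampling runs first so interpolation happens in Hounsfield units;
clipping and rescaling afterwards. Acquisitions with axial spacing
above 5 mm, mixed or non-axial DICOM series, and series with
non-uniform slice gaps are rejected at load time. Axial orientation is
normalized head-to-toe from the NIfTI/DICOM geometry; an unreadable
orientation sets an explicit flag rather than guessing. Dates are ISO
dates; one day is the time granularity everywhere.

## Localizer

A small VGG-style 2-D convnet scores individual axial slices. It is
trained siamese-style on pairs of slices from the same scan with binary
cross-entropy on `sigmoid(s_b − s_a)` against the "slice a is superior"
label — the only way to solve this task is to assign each anatomical
level a score increasing head to toe. Training follows Adam at
lr 10⁻³ with batches of 8 scans × one random slice pair each, 50,000
iterations at full scale (tests use 1,500 iterations on gradient
phantoms, which already reach ≥ 0.99 held-out ordering accuracy).

Scores are mapped to axial coordinates with a RANSAC line
(score ≈ a·z + b); the residual threshold defaults to twice the median
absolute residual of an initial least-squares fit, and exactly linear
inputs short-circuit to least squares so noiseless recovery is exact.
Landmarks (lower neck, upper/lower diaphragm, lower pelvis) are stored
as target scores; the upper diaphragm anchors near score 25 in the
original formulation. Since absolute scores depend on the trained
network, targets for all four landmarks are calibrated on annotated
fixtures: the target is the fitted-line value at the known plane,
averaged over calibration scans. Because calibration and application
both go through per-scan fitted lines, a monotone but non-linear score
profile cancels out as long as scans cover the same anatomical span.
Chest is cropped between lower neck and lower diaphragm, abdomen
between upper diaphragm and lower pelvis (the two overlap at the
diaphragm slab by construction); a region whose landmark span lies more
than half outside the scan is reported absent with a reason rather
than cropped.

## Tracker

Registration is two-stage on channel-stacked pairs, moving = prior
scan, fixed = subsequent scan (change is expressed forward in time):

- **Affine branch:** five strided conv blocks + two fully connected
  layers regress 12 parameters. The head is zero-initialized and
  outputs *deviations from identity*, with translations expressed in
  half-extent units, so the untrained network is exactly the identity
  and all 12 parameters have comparable gradient leverage. (With raw
  voxel units, Adam moves every parameter at the same rate, and a
  plausible multi-voxel translation would need hundreds of steps while
  the linear part overshoots.)
- **Deformable branch:** a U-Net (encoder widths 16/32/64/96, each
  halving resolution by striding; a stride-1 latent block of 96
  channels; a mirrored transposed-conv decoder with skip connections)
  regresses a dense displacement field in voxels on the fixed grid. The
  final field layer is zero-initialized: the untrained model is the
  identity map. The 96-channel latent block is the deepest layer whose
  feature maps feed prognostication.

Warping is trilinear with zero outside the field of view; sampling at
exact grid points reproduces values bit-for-bit. All network code runs
on a small reverse-mode autodiff core (`pam._autodiff`) written on
numpy — convolutions as sums over kernel offsets, transposed
convolutions as their exact adjoints, and an analytic warp gradient —
every primitive is finite-difference checked in the unit suite.

**Objective.** 1 − global correlation coefficient between the warped
moving and fixed images (invariant to affine intensity rescaling;
both-constant inputs are flagged and scored 1), plus three penalties:
deviation of the linear part from identity and squared translation
(each weighted 1/10; inside the objective the translation is in
half-extent units — see above — while the reported metric
`regularization_penalties` uses raw voxel units), and the mean squared
forward-difference gradient of the field (weighted 1/100). A curriculum
smooths the *loss inputs* (not the network inputs) with a box kernel of
9, dropping to 6, 3, and none at epochs 100/150/175 of a nominal
200-epoch schedule; desk runs rescale the boundaries proportionally.
Training is Adam at 3×10⁻⁴, batch 2, group normalization (groups of 8,
or the channel count when narrower) in every conv block. Subjects whose
numeric ID is a multiple of 10 are held out and only monitored.
Pre-training pairs are drawn across subjects — registering scans of
different patients is a deliberately harder auxiliary task than
follow-up matching.

`recover_affine` performs the model-free oracle: direct gradient
descent on the 12 parameters for a single pair, smoothed-correlation
loss only (no penalties — the oracle measures attainable alignment).
On 32³ phantoms it recovers a planted 4-voxel translation to well
within one voxel; the desk-trained network must not be worse than
2 voxels mean target-registration error on the same kind of fixtures.

## Survival association

For one patient and region, every ordered pair of scans taken between
6 months before and 2 years after treatment start (183/730 days) with
0 < Δt ≤ 365 days is eligible. The label is death within 365 days of
the later scan; living patients censored less than a year after the
later scan are not evaluable and the pair is dropped. Global average
pooling of the 96 latent maps plus the two temporal covariates (days
from treatment start to the later scan, days between scans) gives a
98-dimensional input to an L2-regularized logistic model on
standardized inputs. The default regularization (C = 0.01 in sklearn's
parameterization) is deliberately heavy: cohorts supply few pairs
relative to the 98 inputs, pairs of one patient are strongly
dependent, and under those conditions only directions close to the
stable univariate associations generalize to unseen patients — a
behaviour verified on several independent synthetic cohorts, with the
held-out half never consulted when fixing the default. Analyses with
ample independent samples should override ``C``.
Multiple pairs of one patient aggregate by averaging predictions;
abdominal and thoracic patient scores combine by averaging. The
discovery/test split is by patient-ID parity (even = discovery).

## Explainability

Occlusion sensitivity: a cubic patch (default 64 voxels, stride 8) is
zeroed in both scans at the same location, the model is re-scored, and
the patch importance is |occluded − reference|. Per-voxel importance is
the maximum over all covering patch positions. Patch positions start at
every multiple of the stride and are clipped at the volume boundary, so
every voxel (including the 160-slice chest grid) is covered. The
implementation is kept sequential and is tested bit-identical against
an independent transliteration of the scrolling pseudocode.

## Statistics

AUC is computed with midranks and equals the Mann-Whitney U statistic
over n₊·n₋ (asserted on random instances). Sensitivity/specificity use
the Youden-optimal threshold on discovery data, frozen for test data.
Confidence intervals are percentile bootstrap over 1,000 resamples at
the scan-pair level (degenerate resamples are skipped and counted).
Significance is the two-sided asymptotic Mann-Whitney test; temporal
analysis slides a half-open 183-day window forward 7 days at a time,
evaluating windows with at least 10 samples of each class, with
Benjamini-Hochberg FDR at α = 0.10 across windows. Correlated ROC
curves are compared with a z-test using the DeLong covariance
estimate. Comparator biomarkers: blood-value rates (v_s − v_p)/Δt with
values averaged over ±21 days of each scan date (missing windows give
missing values; complete-case analysis per comparator), and
volume-derived RECIST classes using the sphere-equivalent diameter
d = (6V/π)^(1/3) — progression above a 1.2 diameter ratio, response
below 0.7. The multivariate comparison is a joint logistic fit after
standardizing and averaging feature pairs with |r| > 0.9; perfect
separation is detected and flagged rather than interpreted.
Kaplan-Meier risk-group splits report the two-sided log-rank p and
per-group median survival ("not reached" is +inf).

## Synthetic phantoms and cohorts

Phantoms are [0, 1]-intensity volumes with an elliptical body outline,
a monotone head-to-toe gradient with internal banding (so slice order
is learnable but not trivially linear), optional organ-like blobs, and
spherical lesions whose radius evolves linearly in time. Landmark
planes default to fixed anatomical fractions of the axial extent and
ship as machine-readable ground truth. Follow-up pairs are built as
`subsequent(x) = prior_grown(x + u(x))`, where u composes a known
affine (about the volume center) with gaussian-filtered white noise of
configurable amplitude and smoothness (≥ 2 voxels); landmark
correspondences come with the pair, and fixtures whose displacement
exceeds a quarter of the extent are rejected as unrecoverable.

Cohorts draw a patient-specific lesion growth rate (normal, sd
0.02 voxels/day), place 3-4 scans ~75 days apart starting around
treatment start, and simulate exponential survival with rate
λ₀·exp(β·z), λ₀ = 1/400 per day, β = 1.5 per SD of growth rate,
censoring at 730 days. Fitting a Cox model on the true covariate
recovers β within two standard errors at n = 200 (tested). Patient IDs
are consecutive integers so the parity split is exercisable.

**Desk scale.** All tests and the acceptance script run the production
code paths on reduced problem sizes, chosen as the package's own desk
defaults: 64×32×32 whole-body grids, 32³ region crops, 1,200-1,500
localizer iterations, 200-300 tracker steps, 80-patient cohorts. The
end-to-end synthetic study therefore shows that the pipeline machinery
(harmonization, localization, registration, feature pooling,
classification, statistics) is correctly wired and that genuine
morphological-change signal survives the whole chain at small scale; it
does not show clinical-level effect sizes, scanner/protocol
heterogeneity, contrast-phase or artifact robustness, or the anatomy
realism of real CT. Held-out discrimination on phantom cohorts is
accordingly modest (AUC ≈ 0.6, significant by permutation test) rather
than at the level a full-scale system reports.

## Known limitations

- The numpy autodiff core is single-threaded and sized for desk-scale
  volumes; full 192³ training is out of reach without a GPU tensor
  backend.
- Global (not windowed) correlation is the default similarity; local
  windows are a config option left untested at scale.
- The deformable model offers no diffeomorphic or inverse-consistency
  guarantees, and no Jacobian/topology checks.
- RECIST comparator is the volume-derived two-class rule only — no
  nadir tracking or target-lesion selection.
- Bootstrap and Mann-Whitney treat scan pairs as independent even when
  they share a patient.
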