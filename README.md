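# pam-monitor

Prognostic monitoring of longitudinal thoraco-abdominal CT: quantify
morphological change between a patient's follow-up scans with a learned
registration network, and link those changes to 1-year overall
survival.

## Who this is for

Imaging researchers studying treatment monitoring in advanced cancer
(e.g. checkpoint-inhibitor therapy), where routine follow-up CT carries
far more information — tumor spread, complications, side effects — than
the few lesion diameters tracked by RECIST. The package provides the
full pipeline plus a synthetic phantom generator, so every stage is
testable on a laptop with no clinical data.

## The method

1. **Harmonize**: isotropic linear resampling at 2 mm, Hounsfield
   clipping to [−120, 300], rescaling to [0, 1], crop/pad to
   192×192×192 (chest: 160 axial slices).
2. **Localize**: a 2-D convnet trained by self-supervised slice
   ordering assigns each axial slice an anatomical score *s* increasing
   head to toe; a RANSAC line s ≈ a·z + b maps scores to coordinates,
   and calibrated landmark scores (lower neck, diaphragm, lower pelvis)
   cut standardized chest and abdomen subvolumes.
3. **Track**: a two-stage registration network — an affine branch
   regressing the 12 transform parameters, then a U-Net regressing a
   dense displacement field u(x) — aligns the prior (moving) onto the
   subsequent (fixed) scan by minimizing 1 − cc(warped, fixed) with
   identity/translation penalties (1/10) and a field-smoothness penalty
   (1/100), under a curriculum that smooths the loss inputs with box
   kernels 9 → 6 → 3 → none.
4. **Predict**: global average pooling of the 96 deepest-layer feature
   maps + two temporal covariates feed an L2 logistic model for death
   within 365 days of the later scan. Pairs are any two scans ≤ 1 year
   apart within [−183, +730] days of treatment start; censored
   patients with < 1 year follow-up after the later scan are excluded.
5. **Explain**: occlusion sensitivity — zero a 64³ patch (stride 8) in
   both scans, re-score, and record per-voxel max |Δprediction|.
6. **Evaluate**: midrank ROC-AUC with 1,000-resample bootstrap CIs,
   Mann-Whitney significance, moving 6-month windows with
   Benjamini-Hochberg FDR (α = 0.10), correlated-ROC comparison,
   blood-value rate and volume-derived RECIST comparators, multivariate
   logistic comparison, and Kaplan-Meier/log-rank risk splits.

The neural components run on a small numpy reverse-mode autodiff core
shipped with the package (gradient-checked in the test suite), sized
for desk-scale volumes.

## Worked example

Run the complete synthetic study — cohort simulation, harmonization,
localizer training, abdominal cropping, tracker pre-training, feature
extraction, classification, evaluation — at desk scale:

```python
from pam.pipeline import EndToEndConfig, run_end_to_end

res = run_end_to_end(EndToEndConfig(seed=1))
print(f"localizer held-out ordering accuracy: "
      f"{res['localizer_holdout_accuracy']:.3f}")
print(f"test pairs: {res['n_test_pairs']}, AUC {res['test_auc']:.3f}, "
      f"permutation p {res['permutation_p']:.4f}")
```

prints (about 5 minutes on one CPU)

```
localizer held-out ordering accuracy: 0.990
test pairs: 204, AUC 0.632, permutation p 0.0100
```

Here 120 synthetic patients carry lesions growing at patient-specific
rates; survival is exponential with log-hazard 1.5 per SD of growth
rate. The localizer orders unseen slices almost perfectly; the
classifier, trained on even-ID patients only, discriminates 1-year
survival on the odd-ID patients' 140 scan pairs clearly better than
chance (permutation test over 200 label shuffles). Desk-scale AUCs are
deliberately modest — the phantoms are small and the effect subtle —
the point is that genuine morphological-change signal survives every
stage of the pipeline.

The same stages are scriptable from the shell via the `pam` command
(`pam simulate`, `pam harmonize`, `pam train-localizer`, `pam localize`,
`pam train-tracker`, `pam track`, `pam fit`, `pam predict`,
`pam evaluate`, `pam heatmap`); see `pam --help`.

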