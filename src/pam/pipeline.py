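"""End-to-end orchestration on synthetic cohorts.

Runs the full chain — harmonize, localize/crop, track, pool features,
classify — on a simulated follow-up cohort whose survival hazard
depends on lesion growth, and evaluates the held-out discrimination.
Desk-scale problem sizes (64x32x32 whole-body grids, 32^3 abdominal
crops, shortened training) keep the whole run CPU-friendly while using
exactly the production code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import mann_whitney_p, roc_auc, survival_split
from .grids import ScanRecord
from .harmonize import harmonize
from .localizer import (LocalizerConfig, calibrate_landmarks, crop_regions,
                        fit_score_line, score_slices, train_localizer)
from .phantom import PhantomSpec, SyntheticCohortSpec, make_cohort, make_phantom
from .prognosis import (aggregate_patient, build_pairs, extract_features,
                        fit_classifier, predict_risk, split_by_parity)
from .tracker import TrackerConfig, make_cross_subject_pairs, train_tracker

#: desk-scale harmonized grids (axial axis first)
DESK_REGION_SHAPES = {
    "whole": (64, 32, 32),
    "abdomen": (32, 32, 32),
    "chest": (16, 32, 32),
}


@dataclass
class EndToEndConfig:
    seed: int = 0
    n_patients: int = 120
    shape: tuple = (64, 32, 32)
    region_shapes: dict = field(default_factory=lambda: dict(DESK_REGION_SHAPES))
    log_hazard_per_sd: float = 1.5
    localizer_iterations: int = 1200
    localizer_corpus: int = 10
    tracker_steps: int = 300
    tracker_pairs: int = 48
    n_permutations: int = 200


def permutation_p_auc(scores, labels, n_permutations: int = 200,
                      seed: int = 0) -> float:
    """One-sided permutation p for AUC > 0.5: shuffle labels, recompute."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    observed, _, _ = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if len(np.unique(perm)) < 2:
            continue
        auc, _, _ = roc_auc(scores, perm)
        hits += auc >= observed
    return (hits + 1) / (n_permutations + 1)


def run_end_to_end(config: EndToEndConfig = None) -> dict:
    """Full synthetic study: returns the metrics a real deployment would
    report (held-out AUC, permutation significance, risk-group split)."""
    config = config or EndToEndConfig()
    seed = config.seed

    # 1. simulated cohort with survival tied to lesion growth
    cohort_spec = SyntheticCohortSpec(
        n_patients=config.n_patients, shape=config.shape,
        log_hazard_per_sd=config.log_hazard_per_sd, seed=seed)
    records, truth = make_cohort(cohort_spec)

    # 2. harmonization onto the standard (desk-scale) grid
    for rec in records.values():
        for scan in rec.scans:
            scan.volume = harmonize(scan.volume, "whole",
                                    region_shapes=config.region_shapes)

    # 3. localizer: train on a scan corpus, calibrate landmark scores on
    # annotated phantoms, crop the abdomen of every scan
    loc_cfg = LocalizerConfig(iterations=config.localizer_iterations,
                              seed=seed)
    corpus = [rec.scans[0].volume
              for rec in list(records.values())[:config.localizer_corpus]]
    localizer = train_localizer(corpus, loc_cfg)
    calib = []
    for i in range(3):
        pspec = PhantomSpec(shape=config.shape, seed=9000 + seed * 31 + i)
        calib.append((make_phantom(pspec), pspec.landmark_planes))
    targets = calibrate_landmarks(localizer, calib, loc_cfg)

    abdomen_records = {}
    for pid, rec in records.items():
        scans = []
        for scan in rec.scans:
            smap = fit_score_line(score_slices(localizer, scan.volume),
                                  loc_cfg)
            _, abdomen = crop_regions(scan.volume, smap, targets,
                                      region_shapes=config.region_shapes)
            if abdomen.present:
                scans.append(ScanRecord(date=scan.date, volume=abdomen.volume,
                                        region="abdomen"))
        abdomen_records[pid] = replace(rec, scans=scans)

    # 4. tracker pre-trained, label-free, on cross-subject pairs drawn
    # from the whole scan pool (the production system uses an external
    # unlabeled archive the same way)
    discovery, test = split_by_parity(abdomen_records)
    pool = [(pid, s.volume) for pid, rec in abdomen_records.items()
            for s in rec.scans]
    train_pairs = make_cross_subject_pairs(pool, config.tracker_pairs,
                                           seed=seed)
    tracker = train_tracker(train_pairs,
                            TrackerConfig(steps=config.tracker_steps,
                                          seed=seed),
                            region="abdomen")

    # 5. eligible pairs -> latent features -> classifier
    def featurize(recs):
        feats, labels, pids, days = [], [], [], []
        for pid, rec in recs.items():
            for pair, label in build_pairs(rec, "abdomen"):
                feats.append(extract_features(tracker, pair))
                labels.append(label)
                pids.append(pid)
                days.append(pair.days_from_treatment_start)
        return feats, labels, pids, days

    f_disc, y_disc, _, _ = featurize(discovery)
    f_test, y_test, pid_test, _ = featurize(test)
    classifier = fit_classifier(f_disc, y_disc, seed=seed)
    scores = np.array([predict_risk(classifier, f) for f in f_test])
    labels = np.array([l.positive for l in y_test], dtype=int)
    auc, sens, spec = roc_auc(scores, labels)
    perm_p = permutation_p_auc(scores, labels,
                               n_permutations=config.n_permutations,
                               seed=seed + 1)
    mw_p = mann_whitney_p(scores[labels == 1], scores[labels == 0])

    # 6. patient-level aggregation and risk-group survival split
    by_patient = {}
    for pid, s in zip(pid_test, scores):
        by_patient.setdefault(pid, []).append(s)
    patient_scores = {pid: aggregate_patient(v)
                      for pid, v in by_patient.items()}
    split = None
    if len(patient_scores) >= 4:
        threshold = float(np.median(list(patient_scores.values())))
        try:
            split = survival_split(patient_scores,
                                   {pid: records[pid]
                                    for pid in patient_scores}, threshold)
        except ValueError:
            split = None

    parity_ok = (all(r.numeric_id % 2 == 0 for r in discovery.values())
                 and all(r.numeric_id % 2 == 1 for r in test.values())
                 and len(discovery) + len(test) == len(records))

    return {
        "localizer_holdout_accuracy": localizer.holdout_accuracy,
        "landmark_targets": targets,
        "n_discovery_pairs": len(f_disc),
        "n_test_pairs": len(f_test),
        "test_auc": auc,
        "test_sensitivity": sens,
        "test_specificity": spec,
        "permutation_p": perm_p,
        "mann_whitney_p": mw_p,
        "parity_split_exact": parity_ok,
        "log_rank_p": None if split is None else split.log_rank_p,
        "median_survival_high_risk": None if split is None
        else split.median_high_risk,
        "median_survival_low_risk": None if split is None
        else split.median_low_risk,
        "truth": truth,
        "scores": scores,
        "labels": labels,
        "tracker_loss_history": tracker.loss_history,
    }
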