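"""From scan pairs to 1-year survival predictions.

Eligible pairs are any two scans of one region at most one year apart,
taken between 6 months before and 2 years after the start of treatment.
The label is death within 365 days of the later scan; pairs of living
patients censored less than a year after the later scan are not
evaluable and are dropped. Each pair yields 96 globally-average-pooled
latent tracker features plus two temporal covariates, fed to an
L2-regularized logistic model; multiple pairs of one patient are
aggregated by averaging predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .grids import (LatentFeatureVector, PatientRecord, ScanPair,
                    SurvivalLabel)
from .tracker import TrackerModel

DAYS_1Y = 365
DAYS_6M = 183
DAYS_2Y = 730


def build_pairs(record: PatientRecord, region: str,
                window_before: int = DAYS_6M,
                window_after: int = DAYS_2Y,
                max_gap_days: int = DAYS_1Y) -> list:
    """All eligible (ScanPair, SurvivalLabel) for one patient.

    Scans are restricted to [-window_before, +window_after] days around
    treatment start; ordered pairs need 0 < dt <= max_gap_days; pairs of
    living patients with under a year of follow-up after the later scan
    are excluded as non-evaluable.
    """
    scans = record.scans_of_region(region)
    scans = [s for s in scans
             if -window_before <= (s.date - record.treatment_start).days
             <= window_after]
    if len(scans) < 2:
        return []
    out = []
    for i in range(len(scans)):
        for j in range(i + 1, len(scans)):
            prior, subsequent = scans[i], scans[j]
            dt_days = (subsequent.date - prior.date).days
            if not 0 < dt_days <= max_gap_days:
                continue
            follow_up = (record.death_or_censor - subsequent.date).days
            if record.deceased:
                label = SurvivalLabel(positive=follow_up <= DAYS_1Y,
                                      evaluable=True)
            else:
                if follow_up < DAYS_1Y:
                    continue  # censored too early: not evaluable
                label = SurvivalLabel(positive=False, evaluable=True)
            pair = ScanPair(
                patient_id=record.patient_id,
                prior=prior.volume, subsequent=subsequent.volume,
                prior_date=prior.date, subsequent_date=subsequent.date,
                days_from_treatment_start=(subsequent.date
                                           - record.treatment_start).days,
                days_between_scans=dt_days,
                region=region)
            out.append((pair, label))
    return out


def extract_features(model: TrackerModel, pair: ScanPair) -> LatentFeatureVector:
    """Global average pooling of the 96 deepest-layer tracker maps,
    plus the two temporal covariates."""
    if model.region not in ("unknown", pair.region) \
            and pair.region != "unknown":
        raise ValueError(f"tracker is for {model.region!r}, "
                         f"pair is {pair.region!r}")
    output = model.track(pair)
    pooled = output.latent_maps.reshape(output.latent_maps.shape[0], -1) \
        .mean(axis=1)
    return LatentFeatureVector(features=pooled,
                               t_start=float(pair.days_from_treatment_start),
                               t_delta=float(pair.days_between_scans))


@dataclass
class RiskClassifier:
    """Standardizer + L2 logistic regression over the 98 inputs."""

    mean_: np.ndarray
    scale_: np.ndarray
    coef_: np.ndarray
    intercept_: float

    @property
    def n_features(self) -> int:
        return len(self.coef_)

    def decision(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(rows)
        if rows.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} inputs, "
                             f"got {rows.shape[1]}")
        z = (rows - self.mean_) / self.scale_
        return z @ self.coef_ + self.intercept_

    def predict_proba(self, rows: np.ndarray) -> np.ndarray:
        z = np.clip(self.decision(rows), -500, 500)
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": "risk_classifier", "version": 1,
                       "mean": self.mean_.tolist(),
                       "scale": self.scale_.tolist(),
                       "coef": self.coef_.tolist(),
                       "intercept": self.intercept_}, fh)

    @classmethod
    def load(cls, path) -> "RiskClassifier":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean_=np.asarray(d["mean"]), scale_=np.asarray(d["scale"]),
                   coef_=np.asarray(d["coef"]),
                   intercept_=float(d["intercept"]))


def fit_classifier(features, labels, C: float = 0.01,
                   seed: int = 0) -> RiskClassifier:
    """Fit the survival classifier on feature vectors.

    Inputs are standardized (the 96 latent features together with the
    two temporal covariates); the positive class is death within a year
    of the later scan, so a higher score means higher risk. The default
    L2 strength (C=0.01) is deliberately heavy: cohorts supply few
    pairs relative to the 98 inputs and pairs of one patient are
    strongly dependent, so the fitted direction must stay close to the
    stable univariate associations to generalize across patients.
    Override ``C`` when data are plentiful.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    X = np.stack([f.as_row() if isinstance(f, LatentFeatureVector)
                  else np.asarray(f, dtype=np.float64) for f in features])
    y = np.asarray([l.positive if isinstance(l, SurvivalLabel) else l
                    for l in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes are required to fit")
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(scaler.transform(X), y)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    return RiskClassifier(mean_=scaler.mean_, scale_=scale,
                          coef_=clf.coef_[0],
                          intercept_=float(clf.intercept_[0]))


def predict_risk(classifier: RiskClassifier, feature) -> float:
    """Probability of death within 1 year of the later scan."""
    row = feature.as_row() if isinstance(feature, LatentFeatureVector) \
        else np.asarray(feature, dtype=np.float64)
    return float(classifier.predict_proba(row[None])[0])


def aggregate_patient(predictions) -> float:
    """Patient-level score: arithmetic mean over the pair predictions."""
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to aggregate")
    return float(np.mean(predictions))


def combine_region_scores(abdomen: float, thorax: float) -> float:
    """Combined whole-body score: average of the two region scores."""
    for v in (abdomen, thorax):
        if not 0.0 <= v <= 1.0:
            raise ValueError("region scores must be probabilities in [0,1]")
    return (abdomen + thorax) / 2.0


def split_by_parity(records: dict) -> tuple:
    """Discovery/test split on patient-ID parity: even IDs discovery,
    odd IDs independent test."""
    discovery = {pid: r for pid, r in records.items()
                 if r.numeric_id % 2 == 0}
    test = {pid: r for pid, r in records.items() if r.numeric_id % 2 == 1}
    return discovery, test


def features_to_frame(pairs, labels, vectors):
    """Feature matrix as a DataFrame: one row per pair with ids, dates,
    the 96 features, covariates and label."""
    import pandas as pd

    rows = []
    for (pair, label, vec) in zip(pairs, labels, vectors):
        row = {"patient_id": pair.patient_id,
               "prior_date": pair.prior_date.isoformat(),
               "subsequent_date": pair.subsequent_date.isoformat(),
               "region": pair.region,
               "t_start": vec.t_start, "t_delta": vec.t_delta,
               "label": int(label.positive)}
        row.update({f"feat_{i:02d}": v for i, v in enumerate(vec.features)})
        rows.append(row)
    return pd.DataFrame(rows)
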