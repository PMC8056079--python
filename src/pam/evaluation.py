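"""Statistical evaluation: ROC/AUC with bootstrap CIs, Mann-Whitney
significance, moving 6-month temporal windows with Benjamini-Hochberg
FDR, comparator biomarkers (blood-value rates, volume-derived RECIST
classes), correlated ROC comparison, multivariate logistic comparison,
and Kaplan-Meier risk-group splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import ANALYTES, PatientRecord, ScanPair

ALPHA_FDR = 0.10
WINDOW_DAYS = 183
STEP_DAYS = 7
MIN_CLASS_N = 10
BLOOD_WINDOW_DAYS = 42
N_BOOTSTRAP = 1000


def _check_two_classes(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def youden_threshold(scores, labels) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1."""
    from sklearn.metrics import roc_curve

    y = _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return float(thr[np.argmax(tpr - fpr)])


def roc_auc(scores, labels, threshold: float = None) -> tuple:
    """(AUC, sensitivity, specificity).

    AUC uses midranks (equivalent to the Mann-Whitney U statistic
    normalized by n_pos * n_neg). The operating point is the Youden
    threshold on the given data unless a frozen ``threshold`` from the
    discovery set is supplied.
    """
    from sklearn.metrics import roc_auc_score

    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, s))
    if threshold is None:
        threshold = youden_threshold(s, y)
    pred = s >= threshold
    sens = float(np.mean(pred[y == 1]))
    spec = float(np.mean(~pred[y == 0]))
    return auc, sens, spec


def bootstrap_ci(scores, labels, statistic, n_resamples: int = N_BOOTSTRAP,
                 seed: int = 0, ci: float = 0.95) -> tuple:
    """Percentile bootstrap interval for statistic(scores, labels),
    resampling cases with replacement. Degenerate resamples (where the
    statistic is undefined, e.g. one class) are skipped with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    statistic(s, y)  # must be valid on the full data
    rng = np.random.default_rng(seed)
    values, skipped = [], 0
    n = len(s)
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(statistic(s[idx], y[idx])))
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped}/{n_resamples} degenerate bootstrap "
                      "resamples skipped")
    lo = (1.0 - ci) / 2.0
    return (float(np.quantile(values, lo)),
            float(np.quantile(values, 1.0 - lo)))


def mann_whitney_p(scores_pos, scores_neg) -> float:
    """Two-sided Mann-Whitney U p-value (normal approximation with tie
    correction)."""
    from scipy.stats import mannwhitneyu

    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be nonempty")
    return float(mannwhitneyu(pos, neg, alternative="two-sided",
                              method="asymptotic").pvalue)


def fdr_correct(p_values, alpha: float = ALPHA_FDR) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``alpha``."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


@dataclass
class TemporalWindowCurve:
    window_start: int
    window_end: int
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pos: int
    n_neg: int
    significant_after_fdr: bool = False


def moving_window_analysis(days, scores, labels,
                           window: int = WINDOW_DAYS,
                           step: int = STEP_DAYS,
                           min_n: int = MIN_CLASS_N,
                           n_resamples: int = N_BOOTSTRAP,
                           seed: int = 0) -> list:
    """AUC over half-open temporal windows [d, d + window) advancing by
    ``step`` days; only windows with at least ``min_n`` samples of each
    class are evaluated, and FDR flags are set across all evaluated
    windows."""
    days = np.asarray(days, dtype=float)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(days) == 0:
        return []
    curves = []
    start = int(np.floor(days.min()))
    last = int(np.ceil(days.max()))
    for w in range(start, last + 1, step):
        mask = (days >= w) & (days < w + window)
        y = labels[mask]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos < min_n or n_neg < min_n:
            continue
        s = scores[mask]
        auc, _, _ = roc_auc(s, y)
        lo, hi = bootstrap_ci(s, y,
                              lambda a, b: roc_auc(a, b)[0],
                              n_resamples=n_resamples, seed=seed)
        p = mann_whitney_p(s[y == 1], s[y == 0])
        curves.append(TemporalWindowCurve(
            window_start=w, window_end=w + window, auc=auc,
            ci_low=lo, ci_high=hi, p_value=p, n_pos=n_pos, n_neg=n_neg))
    if curves:
        flags = fdr_correct([c.p_value for c in curves])
        for c, f in zip(curves, flags):
            c.significant_after_fdr = bool(f)
    return curves


def compare_rocs(scores_a, scores_b, labels) -> float:
    """Two-sided p for the difference of two correlated ROC AUCs
    (z-test with the DeLong covariance estimate)."""
    y = _check_two_classes(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("score vectors and labels must align")

    def placements(s):
        pos, neg = s[y == 1], s[y == 0]
        m, n = len(pos), len(neg)
        v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n
                        for p in pos])
        v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                        for q in neg])
        return v10, v01

    v10_a, v01_a = placements(a)
    v10_b, v01_b = placements(b)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Comparator biomarkers
# ---------------------------------------------------------------------------

def blood_rate_features(record: PatientRecord, pair: ScanPair,
                        window: int = BLOOD_WINDOW_DAYS) -> dict:
    """Rate of change (v_s - v_p) / dt of each blood analyte, where v_p
    and v_s average the measurements within +/- window/2 days of the
    prior and subsequent scan dates. Missing windows give NaN."""
    if pair.days_between_scans == 0:
        raise ValueError("dt = 0: rate undefined")
    half = window / 2.0
    out = {}
    for analyte in ANALYTES:
        vals_p, vals_s = [], []
        for date, a, value in record.blood_values:
            if a != analyte:
                continue
            if abs((date - pair.prior_date).days) <= half:
                vals_p.append(value)
            if abs((date - pair.subsequent_date).days) <= half:
                vals_s.append(value)
        if vals_p and vals_s:
            out[f"{analyte}_rate"] = (np.mean(vals_s) - np.mean(vals_p)) \
                / pair.days_between_scans
        else:
            out[f"{analyte}_rate"] = float("nan")
    return out


def sphere_equivalent_diameter(volume_mm3: float) -> float:
    """Diameter of the sphere with the given volume: (6V/pi)^(1/3)."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))


def recist_classify(v_prior: float, v_subsequent: float) -> str:
    """RECIST-style change class from delineated volumes: progression
    when the sphere-equivalent diameter grows >20%, response when it
    shrinks >30%, otherwise neither."""
    ratio = sphere_equivalent_diameter(v_subsequent) \
        / sphere_equivalent_diameter(v_prior)
    if ratio > 1.2:
        return "progression"
    if ratio < 0.7:
        return "response"
    return "neither"


def merge_collinear(frame, threshold: float = 0.9):
    """Average standardized feature columns whose |Pearson r| exceeds
    ``threshold`` (e.g. hemoglobin and erythrocyte rates)."""
    import pandas as pd

    std = (frame - frame.mean()) / frame.std(ddof=0).replace(0, 1.0)
    cols = list(std.columns)
    merged = {}
    used = set()
    for i, ci in enumerate(cols):
        if ci in used:
            continue
        group = [ci]
        for cj in cols[i + 1:]:
            if cj in used:
                continue
            r = std[ci].corr(std[cj])
            if np.isfinite(r) and abs(r) > threshold:
                group.append(cj)
                used.add(cj)
        name = "+".join(group)
        merged[name] = std[group].mean(axis=1)
    return pd.DataFrame(merged, index=frame.index)


def multivariate_comparison(pam_scores, comparators, labels,
                            collinearity_threshold: float = 0.9):
    """Joint logistic fit of the PAM score against comparator features.

    Complete cases only; collinear comparator columns (|r| > threshold)
    are averaged after standardization. Returns a DataFrame with
    coefficient, SE, 95% CI, p and a separation flag per feature.
    """
    import pandas as pd
    import statsmodels.api as sm

    X = pd.DataFrame(dict(comparators))
    X.insert(0, "pam_score", np.asarray(pam_scores, dtype=float))
    y = pd.Series(np.asarray(labels, dtype=int), index=X.index)
    keep = X.notna().all(axis=1)
    X, y = X[keep], y[keep]
    _check_two_classes(y)
    merged = merge_collinear(X, collinearity_threshold)
    design = sm.add_constant(merged)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200, method="bfgs")
    ci = fit.conf_int()
    table = pd.DataFrame({
        "coefficient": fit.params,
        "std_error": fit.bse,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p_value": fit.pvalues,
    })
    separated = []
    for name in design.columns:
        x = design[name].to_numpy()
        pos, neg = x[y.to_numpy() == 1], x[y.to_numpy() == 0]
        separated.append(bool(len(pos) and len(neg)
                              and (pos.min() > neg.max()
                                   or pos.max() < neg.min())))
    table["separation_flag"] = (np.abs(table["coefficient"]) > 100.0) \
        | np.array(separated)
    return table


@dataclass
class SurvivalSplitResult:
    log_rank_p: float
    median_low_risk: float  # days; inf when not reached
    median_high_risk: float
    n_low: int
    n_high: int


def survival_split(patient_scores: dict, records: dict,
                   threshold: float) -> SurvivalSplitResult:
    """Kaplan-Meier comparison of high-risk (score > threshold) versus
    low-risk patients: two-sided log-rank p and median survival per
    group (inf when the median is not reached)."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    durations, events, high = [], [], []
    for pid, score in patient_scores.items():
        rec = records[pid]
        durations.append((rec.death_or_censor - rec.treatment_start).days)
        events.append(int(rec.deceased))
        high.append(score > threshold)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    high = np.asarray(high, dtype=bool)
    if high.all() or (~high).all():
        raise ValueError("both risk groups must be nonempty")

    def km_median(mask):
        km = KaplanMeierFitter().fit(durations[mask], events[mask])
        return float(km.median_survival_time_)

    lr = logrank_test(durations[high], durations[~high],
                      event_observed_A=events[high],
                      event_observed_B=events[~high])
    return SurvivalSplitResult(
        log_rank_p=float(lr.p_value),
        median_low_risk=km_median(~high),
        median_high_risk=km_median(high),
        n_low=int((~high).sum()), n_high=int(high.sum()))
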