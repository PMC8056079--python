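"""Statistical machinery against closed-form and brute-force oracles."""

import datetime as dt

import numpy as np
import pytest

from pam.evaluation import (blood_rate_features, bootstrap_ci, compare_rocs,
                            fdr_correct, mann_whitney_p, merge_collinear,
                            moving_window_analysis, multivariate_comparison,
                            recist_classify, roc_auc, survival_split,
                            youden_threshold)
from pam.grids import PatientRecord, ScanPair, VolumeGrid

T0 = dt.date(2016, 1, 1)


def day(offset):
    return T0 + dt.timedelta(days=int(offset))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, sens, spec = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0 and sens == 1.0 and spec == 1.0

    def test_all_tied_scores_give_half(self):
        auc, _, _ = roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.random(500)
        y = rng.integers(0, 2, 500)
        auc, _, _ = roc_auc(s, y)
        assert 0.45 < auc < 0.55

    def test_equals_mann_whitney_u_normalized(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        for _ in range(20):
            n_pos, n_neg = rng.integers(3, 30, size=2)
            pos = rng.normal(0.5, 1, n_pos)
            neg = rng.normal(0.0, 1, n_neg)
            s = np.concatenate([pos, neg])
            y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int)
            auc, _, _ = roc_auc(s, y)
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_frozen_threshold_reused(self):
        disc_scores = [0.1, 0.2, 0.6, 0.9]
        disc_labels = [0, 0, 1, 1]
        thr = youden_threshold(disc_scores, disc_labels)
        assert thr == pytest.approx(0.6)
        _, sens, spec = roc_auc([0.15, 0.7, 0.65, 0.95], [0, 1, 0, 1],
                                threshold=thr)
        # frozen threshold 0.6 misclassifies the 0.65 negative, while a
        # threshold re-fit on the test data would not
        assert sens == 1.0 and spec == 0.5


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci([1, 2, 3, 4], [0, 1, 0, 1],
                              lambda s, y: 7.0, n_resamples=50, seed=0)
        assert lo == hi == 7.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        s = np.r_[rng.normal(2, 1, 40), rng.normal(0, 1, 40)]
        auc, _, _ = roc_auc(s, y)
        lo, hi = bootstrap_ci(s, y, lambda a, b: roc_auc(a, b)[0],
                              n_resamples=200, seed=0)
        assert lo <= auc <= hi

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)

        def width(n):
            y = rng.integers(0, 2, n)
            s = rng.normal(0, 1, n) + y
            lo, hi = bootstrap_ci(s, y, lambda a, b: float(np.mean(a)),
                                  n_resamples=300, seed=1)
            return hi - lo

        assert width(1000) < width(100)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50)
        s = rng.normal(size=50) + y
        a = bootstrap_ci(s, y, lambda p, q: roc_auc(p, q)[0], 100, seed=9)
        b = bootstrap_ci(s, y, lambda p, q: roc_auc(p, q)[0], 100, seed=9)
        assert a == b


class TestMannWhitney:
    def test_complete_separation_tiny_p(self):
        pos = np.arange(20) + 100.0
        neg = np.arange(20.0)
        assert mann_whitney_p(pos, neg) < 1e-3

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        assert mann_whitney_p(a, b) == pytest.approx(mann_whitney_p(b, a))

    def test_null_p_values_center_near_half(self):
        ps = []
        for s in range(60):
            rng = np.random.default_rng(s)
            ps.append(mann_whitney_p(rng.normal(size=40),
                                     rng.normal(size=40)))
        assert 0.3 < np.median(ps) < 0.7

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_p([], [1.0])


def brute_force_bh(p, alpha):
    """Exhaustive step-up search over all cutoffs."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_best = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_best = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_best]] = True
    return reject


class TestFdr:
    def test_hand_computed_example(self):
        flags = fdr_correct([0.01, 0.02, 0.03, 0.5], alpha=0.1)
        # BH thresholds 0.025 / 0.05 / 0.075 / 0.1 -> first three rejected
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_no_rejections(self):
        assert not fdr_correct([1.0] * 6).any()

    def test_matches_exhaustive_step_up(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            m = rng.integers(1, 13)
            p = np.round(rng.random(m), 3)
            got = fdr_correct(p, alpha=0.1)
            np.testing.assert_array_equal(got, brute_force_bh(p, 0.1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


class TestCompareRocs:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 40)
        s = rng.normal(size=40) + y
        assert compare_rocs(s, s.copy(), y) == 1.0

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        perfect = y + rng.normal(0, 0.05, 200)
        random_scores = rng.normal(size=200)
        assert compare_rocs(perfect, random_scores, y) < 0.01

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 60)
        a = rng.normal(size=60) + 0.8 * y
        b = rng.normal(size=60) + 0.3 * y
        assert compare_rocs(a, b, y) == pytest.approx(compare_rocs(b, a, y))


def make_record_with_blood(blood):
    return PatientRecord(patient_id="1", treatment_start=T0,
                         death_or_censor=day(400), deceased=True,
                         blood_values=blood)


def make_pair_dates(prior_day, subsequent_day):
    vol = VolumeGrid(np.zeros((2, 2, 2)), intensity_units="normalized")
    return ScanPair(patient_id="1", prior=vol, subsequent=vol,
                    prior_date=day(prior_day),
                    subsequent_date=day(subsequent_day),
                    days_from_treatment_start=subsequent_day,
                    days_between_scans=subsequent_day - prior_day)


class TestBloodRates:
    def test_hand_computed_rate(self):
        # measurements 60 d apart so the two +/-21 d windows are disjoint
        rec = make_record_with_blood([
            (day(0), "hemoglobin", 8.0),
            (day(60), "hemoglobin", 7.0),
        ])
        pair = make_pair_dates(0, 60)
        feats = blood_rate_features(rec, pair)
        assert feats["hemoglobin_rate"] == pytest.approx(-1.0 / 60.0)

    def test_window_averaging(self):
        rec = make_record_with_blood([
            (day(-20), "leukocyte", 4.0),
            (day(0), "leukocyte", 6.0),
            (day(10), "leukocyte", 8.0),   # all within +/-21 d of day 0
            (day(60), "leukocyte", 9.0),
        ])
        pair = make_pair_dates(0, 60)
        feats = blood_rate_features(rec, pair)
        assert feats["leukocyte_rate"] == pytest.approx((9.0 - 6.0) / 60.0)

    def test_missing_window_gives_nan(self):
        rec = make_record_with_blood([(day(0), "thrombocyte", 300.0)])
        pair = make_pair_dates(0, 100)  # nothing near day 100
        feats = blood_rate_features(rec, pair)
        assert np.isnan(feats["thrombocyte_rate"])

    def test_zero_dt_rejected(self):
        rec = make_record_with_blood([])
        pair = make_pair_dates(0, 30)
        pair.days_between_scans = 0
        with pytest.raises(ValueError):
            blood_rate_features(rec, pair)


class TestRecist:
    def test_volume_doubling_is_progression(self):
        # diameter ratio 2^(1/3) ~ 1.26 > 1.2
        assert recist_classify(1000.0, 2000.0) == "progression"

    def test_unchanged_volume_is_neither(self):
        assert recist_classify(1500.0, 1500.0) == "neither"

    def test_seventy_percent_shrinkage_is_response(self):
        # 0.3^(1/3) ~ 0.669 < 0.7
        assert recist_classify(1000.0, 300.0) == "response"

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            recist_classify(0.0, 100.0)


class TestMovingWindow:
    def test_window_membership_half_open(self):
        days = [0, 10, 183]
        scores = [0.9, 0.1, 0.5]
        labels = [1, 0, 0]
        # min_n=1 keeps this a pure membership check
        curves = moving_window_analysis(days, scores, labels, min_n=1,
                                        n_resamples=10)
        first = curves[0]
        assert first.window_start == 0 and first.window_end == 183
        # day 183 is outside the half-open window [0, 183)
        assert first.n_pos + first.n_neg == 2

    def test_step_arithmetic(self):
        rng = np.random.default_rng(10)
        days = rng.integers(0, 400, 300)
        labels = rng.integers(0, 2, 300)
        scores = rng.random(300)
        curves = moving_window_analysis(days, scores, labels,
                                        n_resamples=10)
        starts = [c.window_start for c in curves]
        assert all((b - a) % 7 == 0 for a, b in zip(starts, starts[1:]))

    def test_min_class_counts_enforced(self):
        curves = moving_window_analysis([1, 2, 3], [0.1, 0.5, 0.9],
                                        [0, 1, 0], n_resamples=10)
        assert curves == []

    def test_planted_effect_peaks_in_overlapping_window(self):
        rng = np.random.default_rng(11)
        days = rng.integers(0, 550, 600)
        labels = rng.integers(0, 2, 600)
        scores = rng.random(600)
        early = days < 183
        scores[early] = 0.25 * scores[early] + 0.75 * labels[early]
        curves = moving_window_analysis(days, scores, labels,
                                        n_resamples=20, seed=0)
        best = max(curves, key=lambda c: c.auc)
        assert best.window_start < 183  # overlaps the planted [0, 183)
        assert best.significant_after_fdr

    def test_single_all_covering_window_equals_plain_auc(self):
        rng = np.random.default_rng(12)
        days = rng.integers(0, 100, 80)  # all inside one window
        labels = rng.integers(0, 2, 80)
        scores = rng.random(80) + labels
        curves = moving_window_analysis(days, scores, labels, window=200,
                                        step=500, n_resamples=10)
        assert curves[0].auc == pytest.approx(roc_auc(scores, labels)[0])


class TestMultivariate:
    def test_informative_feature_significant(self):
        rng = np.random.default_rng(13)
        n = 300
        y = rng.integers(0, 2, n)
        pam = 0.3 * y + 0.35 + rng.normal(0, 0.08, n)
        comparators = {"noise_a": rng.normal(size=n),
                       "noise_b": rng.normal(size=n)}
        table = multivariate_comparison(pam, comparators, y)
        assert table.loc["pam_score", "p_value"] < 0.05
        assert table.loc["noise_a", "p_value"] > 0.05

    def test_collinear_features_merged(self):
        import pandas as pd

        rng = np.random.default_rng(14)
        a = rng.normal(size=200)
        frame = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.1, 200),
                              "c": rng.normal(size=200)})
        merged = merge_collinear(frame, threshold=0.9)
        assert "a+b" in merged.columns and "c" in merged.columns
        assert merged.shape[1] == 2

    def test_separation_flagged(self):
        rng = np.random.default_rng(15)
        n = 80
        y = rng.integers(0, 2, n)
        perfect = y.astype(float)  # separates the outcome exactly
        table = multivariate_comparison(
            perfect, {"noise": rng.normal(size=n)}, y)
        assert bool(table["separation_flag"].any())


class TestSurvivalSplit:
    def make_records(self, durations, events):
        recs = {}
        for i, (d, e) in enumerate(zip(durations, events)):
            recs[str(i)] = PatientRecord(patient_id=str(i),
                                         treatment_start=T0,
                                         death_or_censor=day(d),
                                         deceased=bool(e))
        return recs

    def test_identical_groups_p_near_one(self):
        durations = list(range(50, 150, 10)) * 2
        events = [1] * 20
        recs = self.make_records(durations, events)
        scores = {str(i): (0.2 if i < 10 else 0.8) for i in range(20)}
        # identical survival in both halves by construction
        res = survival_split(scores, recs, threshold=0.5)
        assert res.log_rank_p > 0.9

    def test_hazard_ratio_three_detected(self):
        rng = np.random.default_rng(16)
        n = 50
        d_low = rng.exponential(300, n).astype(int) + 1
        d_high = rng.exponential(100, n).astype(int) + 1
        recs = self.make_records(list(d_low) + list(d_high), [1] * (2 * n))
        scores = {str(i): (0.1 if i < n else 0.9) for i in range(2 * n)}
        res = survival_split(scores, recs, threshold=0.5)
        assert res.log_rank_p < 0.01
        assert res.median_high_risk < res.median_low_risk

    def test_event_free_group_median_not_reached(self):
        recs = self.make_records([100, 120, 140, 700, 700, 700],
                                 [1, 1, 1, 0, 0, 0])
        scores = {str(i): (0.9 if i < 3 else 0.1) for i in range(6)}
        res = survival_split(scores, recs, threshold=0.5)
        assert np.isinf(res.median_low_risk)

    def test_empty_group_rejected(self):
        recs = self.make_records([100, 200], [1, 1])
        scores = {"0": 0.9, "1": 0.8}
        with pytest.raises(ValueError):
            survival_split(scores, recs, threshold=0.5)
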