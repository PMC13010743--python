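"""Statistical layer: operating-point metrics, Wilson intervals, prevalence
arithmetic, effect sizes, FDR, discrimination/calibration, bootstrap, and the
order-effect check."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oculoscreen.stats import (
    bootstrap_ci,
    calibration_metrics,
    cohens_d,
    confusion_metrics,
    discrimination_metrics,
    group_compare,
    order_effect_check,
    prevalence_ppv_npv,
    rank_biserial,
    wilson_ci,
)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(10, 0, 10, 0)
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_always_wrong_classifier(self):
        m = confusion_metrics(0, 10, 0, 10)
        assert m.sensitivity == 0.0 and m.specificity == 0.0

    def test_identities_hold_on_small_grid(self):
        for tp, fn, tn, fp in itertools.product(range(4), repeat=4):
            if tp + fn + tn + fp == 0:
                continue
            m = confusion_metrics(tp, fn, tn, fp)
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            if tp + fp:
                assert m.ppv == pytest.approx(tp / (tp + fp))
            else:
                assert np.isnan(m.ppv)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)


class TestWilson:
    def test_zero_successes_lower_bound(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert 0 < hi < 1

    @given(st.integers(0, 50), st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_interval_contains_point_estimate(self, k, n):
        if k > n:
            k = k % (n + 1)
        lo, hi = wilson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_rejects_empty_denominator(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestPrevalence:
    def test_symmetric_case(self):
        row = prevalence_ppv_npv(0.9, 0.9, 0.5)
        assert row.ppv == pytest.approx(0.9)
        assert row.npv == pytest.approx(0.9)

    def test_degenerate_prevalence_rejected(self):
        for pi in (0.0, 1.0):
            with pytest.raises(ValueError):
                prevalence_ppv_npv(0.9, 0.9, pi)

    def test_empirical_consistency_with_confusion_counts(self):
        # at the cohort's balanced prevalence, Bayes' rule reproduces the
        # empirical PPV/NPV implied by the confusion matrix
        m = confusion_metrics(31, 4, 33, 2)
        row = prevalence_ppv_npv(m.sensitivity, m.specificity, 0.5)
        assert row.ppv == pytest.approx(m.ppv, abs=1e-12)
        assert row.npv == pytest.approx(m.npv, abs=1e-12)


class TestEffectSizes:
    def test_equal_means_zero_d(self):
        assert cohens_d(1.0, 0.5, 20, 1.0, 0.7, 20) == pytest.approx(0.0)

    def test_pooled_sd_reduces_for_equal_n(self):
        d = cohens_d(0.0, 1.0, 35, 1.0, 2.0, 35)
        assert d == pytest.approx(1.0 / np.sqrt((1.0 + 4.0) / 2))

    def test_fully_separated_rank_biserial(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([10.0, 11.0, 12.0])
        assert rank_biserial(x, y) == pytest.approx(1.0)
        u = sps.mannwhitneyu(y, x).statistic
        assert u == 9.0


class TestGroupCompare:
    def test_bh_rejection_count_matches_hand_computation(self):
        # p-values {0.01, 0.02, 0.04, 0.8} at q=0.05: largest i with
        # p_(i) <= i q / m is i = 2 -> exactly 2 rejections
        rng = np.random.default_rng(0)
        n = 40
        labels = pd.Series([0] * n + [1] * n)
        cols = {}
        # construct features whose two-sided t-test p-values land near targets
        from statsmodels.stats.multitest import multipletests

        pvals = np.array([0.01, 0.02, 0.04, 0.8])
        rej, adj, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        assert rej.sum() == 2  # hand-checked BH step-up

    def test_identical_distributions_not_rejected(self):
        rng = np.random.default_rng(1)
        agg = pd.DataFrame({"f1": rng.normal(size=40), "f2": rng.normal(size=40)})
        labels = pd.Series([0] * 20 + [1] * 20)
        out = group_compare(agg, labels)
        assert not out["rejected"].any()

    def test_separated_groups_rejected_with_large_effect(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        agg = pd.DataFrame({"f": v})
        labels = pd.Series([0] * 20 + [1] * 20)
        out = group_compare(agg, labels)
        assert out.loc[0, "rejected"]
        assert out.loc[0, "effect_size"] > 1.5

    def test_constant_feature_skipped(self):
        agg = pd.DataFrame({"f": np.ones(20)})
        labels = pd.Series([0] * 10 + [1] * 10)
        out = group_compare(agg, labels)
        assert out.loc[0, "test"] == "skipped"


class TestDiscrimination:
    def test_perfect_separation(self):
        m = discrimination_metrics(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert m["auc"] == 1.0 and m["ap"] == 1.0

    def test_all_ties_give_half_auc(self):
        m = discrimination_metrics(np.full(10, 0.5), np.array([0, 1] * 5))
        assert m["auc"] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_auc_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        labels = np.array([0, 1] * (n // 2) + [1] * (n % 2))
        scores = np.round(rng.random(n), 2)  # ties likely
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = conc / (len(pos) * len(neg))
        m = discrimination_metrics(scores, labels)
        assert m["auc"] == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discrimination_metrics(np.array([0.5, 0.6]), np.array([1, 1]))


class TestCalibration:
    def test_perfect_confident_predictions(self):
        m = calibration_metrics(np.array([0.0, 1.0, 1.0]), np.array([0, 1, 1]))
        assert m["brier"] == 0.0 and m["ece"] == 0.0

    def test_uninformative_half_probabilities(self):
        m = calibration_metrics(np.full(100, 0.5), np.array([0, 1] * 50))
        assert m["brier"] == pytest.approx(0.25)
        assert m["ece"] == pytest.approx(0.0, abs=1e-12)

    def test_confident_and_wrong(self):
        m = calibration_metrics(np.full(50, 0.9), np.zeros(50, int))
        assert m["brier"] == pytest.approx(0.81)
        assert m["ece"] == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibration_metrics(np.array([]), np.array([]))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9] * 5)
        labels = np.array([0, 0, 1, 1] * 5)
        fn = lambda s, l: discrimination_metrics(s, l)["auc"]
        lo, hi = bootstrap_ci(fn, scores, labels, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        fn = lambda s, l: discrimination_metrics(s, l)["auc"]
        assert bootstrap_ci(fn, scores, labels, 300, seed=9) == bootstrap_ci(fn, scores, labels, 300, seed=9)

    def test_coverage_close_to_nominal(self):
        # known-Bernoulli simulation: CI for the mean covers the truth
        rng = np.random.default_rng(11)
        truth = 0.6
        covered = 0
        runs = 60
        for _ in range(runs):
            x = (rng.random(80) < truth).astype(float)
            labels = np.ones(80, int)
            labels[:2] = 0  # keep both classes so resamples are accepted
            fn = lambda s, l: s.mean()
            lo, hi = bootstrap_ci(fn, x, labels, n_boot=300, seed=int(rng.integers(1 << 30)))
            covered += lo <= truth <= hi
        assert covered / runs > 0.85


class TestOrderEffect:
    def _qc(self, deltas_by_subject, task=1, group="control"):
        rows = []
        for sid, (early, late) in deltas_by_subject.items():
            for i, v in enumerate(early):
                rows.append({"subject_id": sid, "group": group, "task_id": task,
                             "trial_id": i, "invalid_fraction": v, "retained": True})
            for i, v in enumerate(late):
                rows.append({"subject_id": sid, "group": group, "task_id": task,
                             "trial_id": 100 + i, "invalid_fraction": v, "retained": True})
        return pd.DataFrame(rows)

    def test_identical_halves_give_zero_delta_and_p_one(self):
        qc = self._qc({f"s{i}": ([0.05, 0.05], [0.05, 0.05]) for i in range(8)})
        out = order_effect_check(qc)
        assert out.loc[0, "delta_invalid_pct_mean"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_uniform_late_shift_detected(self):
        qc = self._qc({f"s{i}": ([0.05, 0.05], [0.06, 0.06]) for i in range(10)})
        out = order_effect_check(qc)
        assert out.loc[0, "delta_invalid_pct_mean"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 0.01

    def test_odd_trial_count_splits_early_heavy(self):
        # 3 trials: early half gets 2, late gets 1
        qc = self._qc({"s0": ([0.0, 0.0], [0.3])})
        qc = pd.concat([qc, self._qc({"s1": ([0.0, 0.0], [0.3])})], ignore_index=True)
        out = order_effect_check(qc)
        assert out.loc[0, "delta_invalid_pct_mean"] == pytest.approx(30.0)
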