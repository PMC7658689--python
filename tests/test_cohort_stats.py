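"""Tests for the two-group, regression and ROC statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octatten import cohort_stats as cs
from octatten import study_defaults
from octatten import synthetic_data as sd


class TestNormality:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cs.normality_test(np.full(20, 3.0))

    @pytest.mark.parametrize("n", [2, 5001])
    def test_sample_size_limits(self, n):
        with pytest.raises(ValueError):
            cs.normality_test(np.arange(n, dtype=float))

    def test_gaussian_calibration(self):
        passes = sum(
            cs.normality_test(np.random.default_rng(s).standard_normal(200))[1] > 0.05
            for s in range(100)
        )
        assert passes >= 90

    def test_exponential_power(self):
        rejects = sum(
            cs.normality_test(np.random.default_rng(s).exponential(size=200))[1] < 0.05
            for s in range(100)
        )
        assert rejects >= 99


def mw_u_by_enumeration(a, b):
    """U statistic by explicit pair enumeration (oracle)."""
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x, y in itertools.product(a, b)
    )


class TestCompareGroups:
    def test_identical_normal_samples_use_t_branch_p_one(self):
        x = np.random.default_rng(0).normal(10, 2, 30)
        res = cs.compare_groups(x, x)
        assert res.test == "t-test"
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_identical_skewed_samples_use_mw_with_u_half(self):
        x = np.random.default_rng(1).exponential(size=30) ** 2
        res = cs.compare_groups(x, x)
        assert res.test == "mann-whitney"
        assert res.statistic == 30 * 30 / 2  # all-ties U
        assert not res.significant

    def test_u_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 6, 4).astype(float)
            b = rng.integers(0, 6, 4).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            res = cs.compare_groups(np.exp(a * 3), np.exp(b * 3))
            if res.test == "mann-whitney":
                assert res.statistic == mw_u_by_enumeration(np.exp(a * 3), np.exp(b * 3))

    def test_published_rnfl_sn_parameters_detected(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.normal(41.32, 5.67, 38)
            b = rng.normal(45.73, 4.61, 43)
            hits += cs.compare_groups(a, b).significant
        assert hits / 200 >= 0.95

    def test_welch_flag(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 5, 40)
        student = cs.compare_groups(a, b, equal_var=True)
        welch = cs.compare_groups(a, b, equal_var=False)
        if student.test == welch.test == "t-test":
            assert student.p_value != welch.p_value


class TestStandardizedBeta:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = cs.standardized_beta(x, 2 * x + 1)
        assert res.beta == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand computation: r = cov(x, y) / (sd_x * sd_y)
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        res = cs.standardized_beta(x, y)
        assert res.beta == pytest.approx(r_hand)
        assert abs(res.beta) <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cs.standardized_beta(np.ones(5), np.arange(5.0))


class TestAUC:
    def test_full_separation(self):
        assert cs.auc([5, 6, 7], [1, 2, 3]).auc == 1.0

    def test_interleaved_hand_case(self):
        res = cs.auc([2.0, 4.0], [1.0, 3.0])  # patients-high orientation
        assert res.auc == 0.75
        assert res.direction == "positive-high"

    def test_orientation_flips_low_scores(self):
        res = cs.auc([1.0, 2.0], [5.0, 6.0])
        assert res.auc == 1.0 and res.direction == "positive-low"

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_auc_u_identity(self, seed):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 8, rng.integers(2, 12)).astype(float)
        neg = rng.integers(0, 8, rng.integers(2, 12)).astype(float)
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        raw = u / (len(pos) * len(neg))
        assert cs.auc(pos, neg).auc == max(raw, 1 - raw)


def naive_delong(scores1, scores2, labels):
    """Literal loop implementation of the DeLong variance machinery (oracle)."""
    pos_idx = [i for i, l in enumerate(labels) if l]
    neg_idx = [i for i, l in enumerate(labels) if not l]
    m, n = len(pos_idx), len(neg_idx)
    aucs, v10s, v01s = [], [], []
    for scores in (scores1, scores2):
        v10 = []
        for i in pos_idx:
            v10.append(
                sum(
                    1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
                    for j in neg_idx
                )
                / n
            )
        v01 = []
        for j in neg_idx:
            v01.append(
                sum(
                    1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
                    for i in pos_idx
                )
                / m
            )
        aucs.append(sum(v10) / m)
        v10s.append(v10)
        v01s.append(v01)

    def cov(u, v):
        mu, mv = sum(u) / len(u), sum(v) / len(v)
        return sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)

    var = [cov(v10s[k], v10s[k]) / m + cov(v01s[k], v01s[k]) / n for k in (0, 1)]
    cov12 = cov(v10s[0], v10s[1]) / m + cov(v01s[0], v01s[1]) / n
    return aucs, var, cov12


class TestDeLong:
    def test_identical_scores_delta_zero_p_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = np.array([True] * 12 + [False] * 18)
        res = cs.delong_test(scores, scores, labels)
        assert res.delta_auc == 0.0
        assert res.p_value == 1.0

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        labels = np.array([True] * 11 + [False] * 14)
        s1 = rng.normal(size=25)
        s2 = 0.5 * s1 + rng.normal(size=25)
        res = cs.delong_test(s1, s2, labels, names=("s1", "s2"))
        aucs, var, cov12 = naive_delong(list(s1), list(s2), list(labels))
        assert res.entries["s1"].auc == pytest.approx(aucs[0])
        assert res.entries["s2"].auc == pytest.approx(aucs[1])
        assert res.entries["s1"].se ** 2 == pytest.approx(var[0])
        assert res.entries["s2"].se ** 2 == pytest.approx(var[1])
        assert res.delta_se**2 == pytest.approx(var[0] + var[1] - 2 * cov12)

    def test_variance_nonnegative_and_ci_contains_auc(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            labels = np.array([True] * 8 + [False] * 8)
            res = cs.delong_test(rng.normal(size=16), rng.normal(size=16), labels)
            for roc in res.entries.values():
                assert roc.se >= 0
                assert roc.ci[0] <= roc.auc <= roc.ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.delong_test([1.0, 2.0], [1.0, 2.0], [True, True])


class TestReportBuilders:
    def test_table1_structure_and_gating(self, small_cohort_metrics):
        rows = cs.build_table1(small_cohort_metrics)
        assert len(rows) == 30  # 3 indices x 2 layers x 5 regions
        for r in rows:
            assert r.test in ("t-test", "mann-whitney")
            assert 0 <= r.p_value <= 1
            assert r.significant == (r.p_value < 0.05)
            if r.index == "thickness":
                assert r.decrease_ratio_pct is not None

    def test_table1_deterministic(self, small_cohort_metrics):
        r1 = cs.build_table1(small_cohort_metrics)
        r2 = cs.build_table1(small_cohort_metrics)
        assert [(r.p_value, r.test) for r in r1] == [(r.p_value, r.test) for r in r2]

    def test_table2_internal_consistency(self, small_cohort_metrics):
        results = cs.build_table2(small_cohort_metrics)
        assert [r.layer for r in results] == ["RNFL", "GCIPL"]
        for res in results:
            a, b = res.pair
            assert res.delta_auc == pytest.approx(
                res.entries[a].auc - res.entries[b].auc
            )
            for roc in res.entries.values():
                assert 0.5 <= roc.auc <= 1.0

    def test_table2_pairing_follows_significant_indices(self):
        # at the published group parameters the RNFL pairing should be
        # thickness vs attenuation (both clearly significant, intensity not)
        hits = 0
        for seed in range(20):
            metrics = sd.simulate_cohort(sd.CohortSpec(), mode="metrics", seed=seed)
            res = {r.layer: r for r in cs.build_table2(metrics)}
            hits += set(res["RNFL"].pair) == {"thickness", "attenuation"}
        assert hits >= 18

    def test_holm_correction_is_monotone(self, small_cohort_metrics):
        raw = cs.build_table1(small_cohort_metrics, holm=False)
        adj = cs.build_table1(small_cohort_metrics, holm=True)
        for r0, r1 in zip(raw, adj):
            assert r1.p_value >= r0.p_value
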