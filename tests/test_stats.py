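import itertools
import math

import numpy as np
import pytest

from mcrscreen import (
    UNDEFINED,
    NonDetectPolicy,
    ValidationError,
    correlation_suite,
    kendall_tau_b,
    mcr_comparison_by_hi_class,
    wilcoxon_rank_sum,
)
from mcrscreen.pipeline import GroupSummary, SampleMetrics
from mcrscreen.risk_core import IndividualMetrics


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant/tie enumeration."""
    n = len(x)
    concordant = discordant = 0
    for i, j in itertools.combinations(range(n), 2):
        s = (x[i] - x[j]) * (y[i] - y[j])
        if s > 0:
            concordant += 1
        elif s < 0:
            discordant += 1
    n0 = n * (n - 1) // 2
    ties_x = sum(c * (c - 1) // 2 for c in np.unique(x, return_counts=True)[1])
    ties_y = sum(c * (c - 1) // 2 for c in np.unique(y, return_counts=True)[1])
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


def brute_force_ranksum_p(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    pooled = list(a) + list(b)
    m = len(a)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = float(rank)
    u_obs = sum(ranks[:m]) - m * (m + 1) / 2
    n = len(b)
    center = m * n / 2
    dev = abs(u_obs - center)
    total = 0
    hits = 0
    for combo in itertools.combinations(range(m + n), m):
        u = sum(ranks[i] for i in combo) - m * (m + 1) / 2
        total += 1
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def metrics_stub(sample_id, hi, mcr_value, n_eff, policy=NonDetectPolicy.CASE1_ZERO):
    im = IndividualMetrics(
        hi=hi, mhq=hi / mcr_value, mcr=mcr_value,
        missed_fraction=1 - 1 / mcr_value, n=n_eff, top_chemical="x",
    )
    return SampleMetrics(sample_id, policy, im, n_eff, n_eff, n_eff)


class TestKendallTauB:
    def test_perfect_concordance(self):
        res = kendall_tau_b([1, 2, 3], [10, 20, 30])
        assert res.tau_b == pytest.approx(1.0)

    def test_perfect_discordance(self):
        res = kendall_tau_b([1, 2, 3], [3, 2, 1])
        assert res.tau_b == pytest.approx(-1.0)

    def test_brute_force_oracle_on_tied_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 26))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = x * rng.choice([-1, 1]) + rng.integers(0, 4, size=n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = kendall_tau_b(x, y)
            assert res.tau_b == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_all_tied_undefined(self):
        res = kendall_tau_b([1, 1, 1], [1, 2, 3])
        assert res.tau_b is UNDEFINED
        assert res.p_value is UNDEFINED

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            kendall_tau_b([1, 2], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValidationError):
            kendall_tau_b([1], [2])

    def test_n_two_tau_defined_p_undefined(self):
        res = kendall_tau_b([1, 2], [5, 3])
        assert res.tau_b == -1.0
        assert res.p_value is UNDEFINED

    def test_antisymmetry_and_monotone_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = kendall_tau_b(x, y).tau_b
        assert kendall_tau_b(x, -y).tau_b == pytest.approx(-base, abs=1e-12)
        assert kendall_tau_b(np.exp(x), y).tau_b == pytest.approx(base, abs=1e-12)
        assert kendall_tau_b(x, y.argsort().argsort().astype(float)).tau_b == pytest.approx(
            base, abs=1e-12
        )


class TestWilcoxonRankSum:
    def test_small_exact_example(self):
        # frozen: 6 equally likely rank assignments, 2 as extreme
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([5, 1, 3], [5, 1, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_rejected(self, rng):
        a = rng.lognormal(0.0, 0.5, size=80)
        b = rng.lognormal(1.5, 0.5, size=80)
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "asymptotic"
        assert res.p_value < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            m = int(rng.integers(2, 9))
            n = int(rng.integers(2, 9))
            pooled = rng.permutation(np.arange(m + n, dtype=float) + rng.random())
            a, b = pooled[:m], pooled[m:]
            res = wilcoxon_rank_sum(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_null_distribution_sums_to_one(self):
        # under enumeration every rank assignment carries equal probability
        m, n = 4, 5
        total = math.comb(m + n, m)
        counts = {}
        for combo in itertools.combinations(range(1, m + n + 1), m):
            u = sum(combo) - m * (m + 1) / 2
            counts[u] = counts.get(u, 0) + 1
        assert sum(counts.values()) == total
        assert sum(c / total for c in counts.values()) == pytest.approx(1.0)

    def test_ties_fall_back_to_asymptotic(self):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 4])
        assert res.method == "asymptotic"


class TestCorrelationSuite:
    def make_metrics(self, n_values, his, mcrs, policy=NonDetectPolicy.CASE1_ZERO):
        return [
            metrics_stub(f"s{i}", hi, m, n, policy)
            for i, (n, hi, m) in enumerate(zip(n_values, his, mcrs))
        ]

    def test_deterministic_monotone_hi(self):
        ns = list(range(5, 25))
        ms = self.make_metrics(ns, [0.01 * n for n in ns], [2.0] * len(ns))
        groups = [GroupSummary(n, 12, 0.01 * n, 2.0) for n in ns]
        results = {(r.analysis, r.level): r for r in correlation_suite(ms, groups)}
        assert results[("hi_vs_n", "per_sample")].tau_b == pytest.approx(1.0)
        assert results[("hi_vs_n", "group_median")].tau_b == pytest.approx(1.0)

    def test_iid_null_small_tau(self, rng):
        n = 300
        ms = self.make_metrics(
            rng.integers(5, 30, size=n).astype(int).tolist(),
            rng.lognormal(0, 1, size=n).tolist(),
            (1 + 3 * rng.random(n)).tolist(),
        )
        results = {(r.analysis, r.level): r for r in correlation_suite(ms, [])}
        r = results[("mcr_vs_n", "per_sample")]
        assert abs(r.tau_b) < 0.1
        assert r.p_value > 0.05

    def test_constant_medians_undefined(self):
        ns = list(range(5, 15))
        ms = self.make_metrics(ns, [0.01 * n for n in ns], [2.0] * len(ns))
        groups = [GroupSummary(n, 12, 0.01 * n, 3.3) for n in ns]
        results = {(r.analysis, r.level): r for r in correlation_suite(ms, groups)}
        assert results[("mcr_vs_n", "group_median")].tau_b is UNDEFINED

    def test_skips_undefined_median_groups(self):
        ns = list(range(5, 15))
        ms = self.make_metrics(ns, [0.01 * n for n in ns], [2.0] * len(ns))
        groups = [GroupSummary(n, 3, UNDEFINED, UNDEFINED) for n in ns]
        results = correlation_suite(ms, groups)
        assert {(r.analysis, r.level) for r in results} == {
            ("hi_vs_n", "per_sample"),
            ("mcr_vs_n", "per_sample"),
            ("mcr_vs_hi", "per_sample"),
        }

    def test_mixed_policy_rejected(self):
        ms = [
            metrics_stub("a", 1.0, 2.0, 5, NonDetectPolicy.CASE1_ZERO),
            metrics_stub("b", 1.0, 2.0, 5, NonDetectPolicy.CASE2_DL_SQRT2),
        ]
        with pytest.raises(ValidationError):
            correlation_suite(ms, [])


class TestMCRComparisonByHIClass:
    def test_separated_groups(self):
        ms = [metrics_stub(f"lo{i}", 0.5, 3.0 + 0.01 * i, 8) for i in range(12)]
        ms += [metrics_stub(f"hi{i}", 2.0, 1.1 + 0.01 * i, 8) for i in range(12)]
        res = mcr_comparison_by_hi_class(ms)
        assert res.group_sizes == (12, 12)
        assert res.p_value < 0.01
        assert res.group_means[0] < res.group_means[1]

    def test_single_class_rejected(self):
        ms = [metrics_stub(f"s{i}", 0.5, 2.0, 8) for i in range(5)]
        with pytest.raises(ValidationError):
            mcr_comparison_by_hi_class(ms)
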