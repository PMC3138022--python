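"""Nonparametric trend and comparison statistics for the assessment.

Kendall tau-b (tie-corrected in both variables) measures monotone trends
between HI, MCR and n, at the individual-sample level and on the medians of
samples grouped by n. A two-sample rank-sum test (Wilcoxon/Mann-Whitney)
compares MCR between samples classified above and below the HI cutoff —
the compared groups are independent samples, so the rank-sum form is used
rather than the signed-rank form.

Implementations are backed by scipy; the test-suite checks them against
independent brute-force enumeration oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats as _sps

from ._markers import UNDEFINED, Marker, is_defined
from .errors import ValidationError
from .pipeline import GroupSummary, SampleMetrics

__all__ = [
    "CorrelationResult",
    "ComparisonResult",
    "kendall_tau_b",
    "wilcoxon_rank_sum",
    "correlation_suite",
    "mcr_comparison_by_hi_class",
]

logger = logging.getLogger(__name__)

#: Both groups at or under this size (and tie-free) use exact enumeration.
EXACT_RANKSUM_MAX_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    """One Kendall tau-b analysis."""

    analysis: str
    tau_b: Union[float, Marker]
    p_value: Union[float, Marker]
    n_pairs: int
    level: str  # "per_sample" | "group_median"


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group rank-sum comparison."""

    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    group_means: tuple[float, float]
    method: str  # "exact" | "asymptotic"


def kendall_tau_b(
    x: Sequence[float],
    y: Sequence[float],
    analysis: str = "kendall",
    level: str = "per_sample",
) -> CorrelationResult:
    """Kendall rank correlation, tau-b variant (tie-corrected).

    The p-value is two-sided from the tie-adjusted normal approximation.
    When either variable is entirely tied tau-b is undefined; the marker is
    returned with a warning rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("kendall_tau_b requires at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("tau-b undefined for %r: a variable is entirely tied", analysis)
        return CorrelationResult(analysis, UNDEFINED, UNDEFINED, int(x.size), level)
    if x.size == 2:
        # the tie-adjusted normal variance is undefined at n = 2; tau is
        # exactly +/-1 here (all-tied inputs were handled above)
        tau = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
        logger.warning("p-value undefined for %r at n = 2", analysis)
        return CorrelationResult(analysis, tau, UNDEFINED, 2, level)
    res = _sps.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(
        analysis=analysis,
        tau_b=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=int(x.size),
        level=level,
    )


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided two-sample rank-sum comparison of ``a`` vs ``b``.

    Uses exact enumeration of the null rank distribution when both groups
    have at most :data:`EXACT_RANKSUM_MAX_N` observations and the pooled
    data is tie-free; otherwise the normal approximation with continuity
    and tie correction. The statistic reported is the Mann-Whitney U of
    group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = (
        a.size <= EXACT_RANKSUM_MAX_N
        and b.size <= EXACT_RANKSUM_MAX_N
        and not _has_ties(pooled)
    )
    method = "exact" if exact else "asymptotic"
    res = _sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return ComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(int(a.size), int(b.size)),
        group_means=(float(a.mean()), float(b.mean())),
        method=method,
    )


def correlation_suite(
    all_metrics: Sequence[SampleMetrics],
    group_summaries: Sequence[GroupSummary],
) -> list[CorrelationResult]:
    """The five trend analyses run for each non-detect case.

    Per sample: HI~n, MCR~n, MCR~HI. On group medians (groups with defined
    medians only): HI~n, MCR~n. Analyses with fewer than two usable points
    are skipped with a warning.
    """
    policies = {m.policy for m in all_metrics}
    if len(policies) > 1:
        raise ValidationError("correlation_suite requires metrics from one policy")

    defined = [m for m in all_metrics if m.defined]
    results: list[CorrelationResult] = []

    if len(defined) >= 2:
        n_eff = [m.n_effective for m in defined]
        hi = [m.metrics.hi for m in defined]
        mcr = [m.metrics.mcr for m in defined]
        results.append(kendall_tau_b(n_eff, hi, "hi_vs_n", "per_sample"))
        results.append(kendall_tau_b(n_eff, mcr, "mcr_vs_n", "per_sample"))
        results.append(kendall_tau_b(hi, mcr, "mcr_vs_hi", "per_sample"))
    else:
        logger.warning("fewer than 2 defined samples; per-sample correlations skipped")

    usable = [g for g in group_summaries if is_defined(g.median_hi)]
    if len(usable) >= 2:
        n_vals = [g.n_value for g in usable]
        results.append(
            kendall_tau_b(n_vals, [g.median_hi for g in usable], "hi_vs_n", "group_median")
        )
        results.append(
            kendall_tau_b(n_vals, [g.median_mcr for g in usable], "mcr_vs_n", "group_median")
        )
    else:
        logger.warning(
            "fewer than 2 groups with defined medians; group-median correlations skipped"
        )
    return results


def mcr_comparison_by_hi_class(
    all_metrics: Sequence[SampleMetrics], hi_cutoff: float = 1.0
) -> ComparisonResult:
    """Rank-sum comparison of MCR between the HI>cutoff and HI<=cutoff groups."""
    defined = [m for m in all_metrics if m.defined]
    above = [m.metrics.mcr for m in defined if m.metrics.hi > hi_cutoff]
    below = [m.metrics.mcr for m in defined if m.metrics.hi <= hi_cutoff]
    if not above or not below:
        raise ValidationError(
            f"both HI classes must be non-empty (above={len(above)}, below={len(below)})"
        )
    return wilcoxon_rank_sum(above, below)
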