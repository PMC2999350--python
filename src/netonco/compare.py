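"""Between-set statistical comparisons of topological measures.

Rank-sum (Mann-Whitney) tests on per-node measure values, two-proportion
chi-square tests for hub fractions, Pearson correlations between
measures, and a two-sample Kolmogorov-Smirnov alternative for comparing
whole degree distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topology import MEASURES, TopologyProfile

EXACT_RANKSUM_MAX_N = 12

__all__ = [
    "ComparisonResult",
    "wilcoxon_rank_sum",
    "chi_square_two_proportions",
    "pearson_correlation",
    "ks_two_sample",
    "compare_profiles",
]


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    set_a: str
    set_b: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float = float("nan")
    mean_b: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _as_array(sample, label: str) -> np.ndarray:
    arr = np.asarray(list(sample), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty sample: {label}")
    return arr


def wilcoxon_rank_sum(
    x: Iterable[float],
    y: Iterable[float],
    measure: str = "",
    set_a: str = "a",
    set_b: str = "b",
) -> ComparisonResult:
    """Two-sided two-sample rank-sum test.

    Exact enumeration when the pooled sample has <= 12 tie-free values;
    otherwise the normal approximation with tie correction and
    continuity correction.
    """
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    exact = pooled.size <= EXACT_RANKSUM_MAX_N and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return ComparisonResult(
        measure=measure, set_a=set_a, set_b=set_b,
        test="wilcoxon_exact" if exact else "wilcoxon",
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        n_a=xa.size, n_b=ya.size,
        mean_a=float(xa.mean()), mean_b=float(ya.mean()),
    )


def chi_square_two_proportions(
    count_a: int,
    n_a: int,
    count_b: int,
    n_b: int,
    continuity: bool = True,
    measure: str = "",
    set_a: str = "a",
    set_b: str = "b",
) -> ComparisonResult:
    """2x2 chi-square test of equal proportions, 1 d.f.

    Yates continuity correction is applied by default.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must lie in [0, n]")
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn("chi-square 2x2 table has an expected cell below 1", stacklevel=2)
    if table.sum(axis=0).min() == 0:
        # degenerate margin (all successes or all failures): no evidence of difference
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return ComparisonResult(
        measure=measure, set_a=set_a, set_b=set_b, test="chi_square",
        statistic=float(stat), p_value=float(p), n_a=n_a, n_b=n_b,
        mean_a=count_a / n_a, mean_b=count_b / n_b,
    )


def pearson_correlation(
    x: Iterable[float], y: Iterable[float], measure: str = "", set_a: str = "x", set_b: str = "y"
) -> ComparisonResult:
    """Pearson product-moment correlation with the two-sided t-transform p."""
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("samples must have equal length")
    if xa.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance sample")
    r, p = stats.pearsonr(xa, ya)
    return ComparisonResult(
        measure=measure, set_a=set_a, set_b=set_b, test="pearson",
        statistic=float(r), p_value=float(p), n_a=xa.size, n_b=ya.size,
        mean_a=float(xa.mean()), mean_b=float(ya.mean()),
    )


def ks_two_sample(
    x: Iterable[float], y: Iterable[float], measure: str = "", set_a: str = "a", set_b: str = "b"
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test on whole value distributions."""
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    res = stats.ks_2samp(xa, ya)
    return ComparisonResult(
        measure=measure, set_a=set_a, set_b=set_b, test="ks",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=xa.size, n_b=ya.size,
        mean_a=float(xa.mean()), mean_b=float(ya.mean()),
    )


def compare_profiles(
    profiles: Mapping[str, TopologyProfile] | Iterable[TopologyProfile],
    pairs: Sequence[tuple[str, str]],
    measures: Sequence[str] = MEASURES,
    hub_cutoffs: Sequence[int] = (5, 12),
) -> pd.DataFrame:
    """One comparison row per (set pair, measure), plus per-cutoff hub rows.

    For the degree measure a KS row on the full degree distributions is
    emitted alongside the rank-sum row (the two address different
    questions and are labeled distinctly).
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.set_name: p for p in profiles}
    for a, b in pairs:
        for label in (a, b):
            if label not in profiles:
                raise ValueError(f"unknown set label: {label!r}")
    results: list[ComparisonResult] = []
    for a, b in pairs:
        pa, pb = profiles[a], profiles[b]
        for m in measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure: {m!r}")
            results.append(wilcoxon_rank_sum(pa.values(m), pb.values(m), m, a, b))
            if m == "k":
                results.append(ks_two_sample(pa.values(m), pb.values(m), m, a, b))
        for cutoff in hub_cutoffs:
            ca, na = pa.hub_stats(cutoff)[0], len(pa.table)
            cb, nb = pb.hub_stats(cutoff)[0], len(pb.table)
            results.append(
                chi_square_two_proportions(
                    ca, na, cb, nb, measure=f"hub_frac_gt{cutoff}", set_a=a, set_b=b
                )
            )
    return pd.DataFrame([r.__dict__ for r in results])
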