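"""Shared statistical helpers: BH adjustment, exact tests, rank statistics."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "fisher_exact_2x2",
    "hypergeom_upper_tail",
    "rank_sum_test",
    "spearman",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values).

    NaN inputs propagate to NaN outputs and are excluded from the ranking.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def fisher_exact_2x2(table, alternative: str = "two-sided"):
    """Two-sided Fisher exact test; returns (odds_ratio, p).

    The odds ratio is the sample odds ratio, with ``inf`` when the
    denominator product is zero and the numerator is positive.
    """
    table = np.asarray(table, dtype=np.int64)
    res = sps.fisher_exact(table, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def hypergeom_upper_tail(overlap: int, universe: int, term_size: int,
                         sample_size: int) -> float:
    """P(X >= overlap) drawing ``sample_size`` from ``universe`` with
    ``term_size`` successes."""
    return float(sps.hypergeom.sf(overlap - 1, universe, term_size, sample_size))


def rank_sum_test(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann–Whitney) test; returns (statistic, p).

    Uses exact enumeration for small samples without ties and the
    tie-corrected normal approximation (with continuity correction)
    otherwise, mirroring common practice.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    small = max(len(x), len(y)) <= 25
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    return float(sps.spearmanr(x, y).statistic)
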