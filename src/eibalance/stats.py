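"""Shared nonparametric statistics: Mann-Whitney rank-sum, BH-FDR,
two-proportion chi-square.

The rank-sum test enumerates the exact null for small samples
(n1 + n2 <= 12) including tied data; otherwise it uses the tie-corrected
normal approximation with continuity correction.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import chi2_contingency, norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "rank_sum_pvalues", "bh_adjust", "two_proportion_test",
           "EXACT_MAX_N"]

EXACT_MAX_N = 12


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2
    if np.ptp(pooled) == 0:
        return mu, 1.0
    ranks = rankdata(pooled)
    u = _u_statistic(ranks, n1)
    if n1 + n2 <= EXACT_MAX_N:
        return u, _exact_p(ranks, n1, u)
    return u, _asymptotic_p(u, n1, n2, pooled)


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Handles ties because the enumeration permutes the (average) ranks of
    the observed pooled sample rather than assuming a continuous null.
    """
    n = len(ranks)
    mu = n1 * (n - n1) / 2
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def _tie_sum(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def _asymptotic_p(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2
    var = n1 * n2 / 12 * ((n + 1) - _tie_sum(pooled) / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)  # continuity correction
    return min(1.0, 2 * norm.sf(z))


def rank_sum_pvalues(values: np.ndarray, group1_mask: np.ndarray) -> np.ndarray:
    """Column-wise two-sided Mann-Whitney p-values for a spots x genes matrix.

    Vectorized tie-corrected asymptotic path; falls back to the exact
    enumeration per column when n1 + n2 <= 12. Columns constant across all
    spots get p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    g1 = np.asarray(group1_mask, dtype=bool)
    n1 = int(g1.sum())
    n2 = values.shape[0] - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 spots")
    n = n1 + n2

    if n <= EXACT_MAX_N:
        out = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            col = values[:, j]
            if np.ptp(col) == 0:
                out[j] = 1.0
            else:
                _, out[j] = rank_sum_test(col[g1], col[~g1])
        return out

    ranks = rankdata(values, axis=0)
    u = ranks[g1].sum(axis=0) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    tie_sums = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        tie_sums[j] = _tie_sum(values[:, j])
    var = n1 * n2 / 12 * ((n + 1) - tie_sums / (n * (n - 1)))
    p = np.ones(values.shape[1])
    ok = var > 0
    z = np.maximum(np.abs(u[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2 * norm.sf(z))
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-proportion chi-square with continuity correction; (chi2, p)."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    res = chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)
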