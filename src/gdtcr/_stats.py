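"""Shared nonparametric test helpers.

Thin wrappers around scipy that pin the conventions used throughout the
package: two-sided alternatives, exact null distributions for small
tie-free samples and normal approximation with tie/continuity correction
otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

EXACT_N_MAX = 25


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p-value when both groups have ≤ 25 observations and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and max(len(x), len(y)) <= EXACT_N_MAX else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    All-zero differences return (0, 1). Exact when n ≤ 25 with no zero or
    tied differences, else normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d[d != 0]
    tie_free = len(np.unique(np.abs(nz))) == len(nz) and len(nz) == len(d)
    method = "exact" if tie_free and len(d) <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(
        x, y, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")
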