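"""Shared statistical tests: rank-sum comparison and Yates chi-square."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test", "yates_chi2"]


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; exact for small tie-free samples.

    Returns (statistic, p).  Uses the Mann-Whitney U formulation so that
    small samples get the exact permutation distribution rather than the
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]) or np.array_equal(np.sort(x), np.sort(y)):
        return 0.0, 1.0  # degenerate or identical samples: no shift evidence
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def yates_chi2(table) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 table with Yates correction.

    Statistic is sum((|O - E| - 0.5)^2 / E) with the continuity correction
    clipped so over-correction cannot drive it negative; p from chi-square
    with 1 degree of freedom.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("all margins must be nonzero")
    expected = row @ col / total
    adj = np.clip(np.abs(obs - expected) - 0.5, 0.0, None)
    stat = float((adj**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p
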