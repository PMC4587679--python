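"""Replicate-null differential interaction statistic.

Given z-score maps for two conditions with two replicates each, the
per-cell differential score is the mean of the four between-condition
z-score differences, standardized against an empirical null built from
within-condition (replicate:replicate) differences at a random sample of
interactions::

    D(i,j)    = mean{ zA1-zB1, zA1-zB2, zA2-zB1, zA2-zB2 }
    null      = { zA1-zA2, zB1-zB2 } at n_null sampled cells
    score     = (D - mean(null)) / scale(null)

Positive scores mark condition-A-enriched interactions.  The null sample
is drawn without replacement from cells defined in all four maps, seeded
for reproducibility.  Because replicate order within a condition is
arbitrary, the null is sign-symmetric; it is symmetrized explicitly, so
its mean is exactly zero, its scale is the RMS replicate difference, and
the score is exactly antisymmetric under a condition swap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import GenomeBinning
from .normalize import ZScoreMap
from .stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = ["DifferentialMap", "differential_score", "subtract_zscores", "interchrom_set_comparison"]

N_NULL = 500_000


@dataclass
class DifferentialMap:
    """Standardized condition-difference matrix with its null summary."""

    binning: GenomeBinning
    scores: np.ndarray
    null_mean: float
    null_scale: float
    n_null: int
    seed: int


def differential_score(
    z_a1: ZScoreMap,
    z_a2: ZScoreMap,
    z_b1: ZScoreMap,
    z_b2: ZScoreMap,
    n_null: int = N_NULL,
    seed: int = 0,
) -> DifferentialMap:
    """Standardized mean between-condition z difference per cell."""
    binning = z_a1.binning
    for z in (z_a2, z_b1, z_b2):
        if z.binning != binning:
            raise ValueError("z-score maps do not share a binning")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    a1, a2, b1, b2 = (z.values for z in (z_a1, z_a2, z_b1, z_b2))
    defined = np.isfinite(a1) & np.isfinite(a2) & np.isfinite(b1) & np.isfinite(b2)
    diff = ((a1 - b1) + (a1 - b2) + (a2 - b1) + (a2 - b2)) / 4.0
    diff[~defined] = np.nan

    # null: replicate differences at sampled upper-triangle cells
    iu = np.triu_indices(binning.n_bins, k=1)
    cand = np.where(defined[iu])[0]
    if cand.size == 0:
        raise ValueError("no cells defined in all four maps")
    if cand.size < n_null:
        logger.warning("differential_score: only %d defined cells < n_null=%d; using all", cand.size, n_null)
        chosen = cand
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(cand, size=n_null, replace=False)
    ci, cj = iu[0][chosen], iu[1][chosen]
    null = np.concatenate([(a1 - a2)[ci, cj], (b1 - b2)[ci, cj]])
    # replicate order within a condition is arbitrary, so the null is
    # sign-symmetric by construction: symmetrize, giving mean exactly 0 and
    # scale = RMS difference (also makes the score exactly antisymmetric
    # under a condition swap)
    null_mean = 0.0
    null_scale = float(np.sqrt(np.mean(null**2))) if null.size else np.nan
    if not null_scale or not np.isfinite(null_scale):
        logger.warning("differential_score: degenerate null (scale=%r); scores unscaled", null_scale)
        null_scale = 1.0
    scores = (diff - null_mean) / null_scale
    return DifferentialMap(binning, scores, null_mean, null_scale, int(len(chosen)), seed)


def subtract_zscores(z_a: ZScoreMap, z_b: ZScoreMap) -> np.ndarray:
    """Direct cellwise z difference (A minus B), NaN-propagating."""
    if z_a.binning != z_b.binning:
        raise ValueError("z-score maps do not share a binning")
    return z_a.values - z_b.values


def interchrom_set_comparison(diff: DifferentialMap, set1: list[str], set2: list[str]):
    """Compare trans differential scores within set1 vs between set1 and set2.

    Collects scores for chromosome pairs with both chromosomes in ``set1``
    ("within") against pairs with one in each set ("cross"); returns both
    samples, their medians, and a two-sided Wilcoxon rank-sum p value.
    """
    if not set1 or not set2:
        raise ValueError("chromosome sets must be non-empty")
    binning = diff.binning

    def pair_scores(chrom_a, chrom_b):
        block = diff.scores[binning.chrom_slice(chrom_a), binning.chrom_slice(chrom_b)]
        return block[np.isfinite(block)]

    within = [pair_scores(a, b) for i, a in enumerate(set1) for b in set1[i + 1:]]
    cross = [pair_scores(a, b) for a in set1 for b in set2]
    within = np.concatenate(within) if within else np.array([])
    cross = np.concatenate(cross) if cross else np.array([])
    if within.size == 0 or cross.size == 0:
        raise ValueError("empty score sample for one of the chromosome sets")
    stat, p = rank_sum_test(within, cross)
    return {
        "within": within,
        "cross": cross,
        "median_within": float(np.median(within)),
        "median_cross": float(np.median(cross)),
        "statistic": float(stat),
        "p_value": float(p),
    }
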