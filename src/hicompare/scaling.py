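"""Distance-scaling curves and telomeric end-to-end contact quantification.

The scaling curve is the mean balanced contact value per log-spaced bin of
genomic separation — genome-wide, per chromosome, or per chromosome arm
(arms from a caller-supplied centromere interval set).  Its log-log slope
summarizes chromatin fiber folding; an upturn at the largest separations of
a whole-chromosome curve that disappears per-arm is the signature of the
two chromosome ends contacting each other.

The telomere statistic quantifies that signature directly: the mean
contact between the first and last ``end_fraction`` (default 5%) of each
chromosome's length, intra-chromosomally, yielding one value per chromosome
that can be compared across conditions with a rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ContactMap, GenomicIntervalSet
from .stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingCurve",
    "TelomereStats",
    "scaling_curve",
    "fit_scaling_slope",
    "telomere_interaction",
    "compare_telomere",
]

END_FRACTION = 0.05
N_LOGBINS = 50


@dataclass
class ScalingCurve:
    """Mean contact per log-spaced distance bin."""

    distance_bp: np.ndarray  # bin centers (geometric)
    mean: np.ndarray
    n_cells: np.ndarray
    scope: str


@dataclass
class TelomereStats:
    """Per-chromosome end-to-end mean contact (first vs last end_fraction)."""

    chromosomes: list[str]
    means: np.ndarray
    end_fraction: float


def _collect_distances(cmap: ContactMap, regions):
    """Distance/value pairs for cis cells of the given (chrom, lo, hi) regions."""
    v = cmap.masked_values()
    binning = cmap.binning
    dists, vals = [], []
    for chrom, lo, hi in regions:
        s = binning.chrom_slice(chrom)
        block = v[s, s][lo:hi, lo:hi]
        nc = block.shape[0]
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :]) * binning.bin_size
        iu = np.triu_indices(nc, k=1)
        keep = np.isfinite(block[iu])
        dists.append(d[iu][keep])
        vals.append(block[iu][keep])
    return (np.concatenate(dists), np.concatenate(vals)) if dists else (np.array([]), np.array([]))


def _arm_regions(cmap: ContactMap, centromeres: GenomicIntervalSet):
    regions = []
    binning = cmap.binning
    for chrom in binning.chromosomes:
        cen = centromeres.subset(chrom)
        if cen.empty:
            logger.warning("scaling_curve: no centromere for %s; whole chromosome used", chrom)
            regions.append((chrom, 0, binning.chrom_nbins(chrom)))
            continue
        start = int(cen["start"].min()) // binning.bin_size
        end = -(-int(cen["end"].max()) // binning.bin_size)
        regions.append((chrom, 0, start))
        regions.append((chrom, end, binning.chrom_nbins(chrom)))
    return regions


def scaling_curve(
    cmap: ContactMap,
    scope: str = "genome",
    n_logbins: int = N_LOGBINS,
    centromeres: GenomicIntervalSet | None = None,
    chrom: str | None = None,
) -> ScalingCurve:
    """Mean cis contact per log-spaced distance bin.

    ``scope`` is "genome", "chromosome" (with ``chrom``) or "arm" (with
    ``centromeres``).
    """
    binning = cmap.binning
    if scope == "genome":
        regions = [(c, 0, binning.chrom_nbins(c)) for c in binning.chromosomes]
    elif scope == "chromosome":
        if chrom is None:
            raise ValueError("chromosome scope needs chrom=")
        regions = [(chrom, 0, binning.chrom_nbins(chrom))]
    elif scope == "arm":
        if centromeres is None:
            raise ValueError("arm scope needs a centromere interval set")
        regions = _arm_regions(cmap, centromeres)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    d, vals = _collect_distances(cmap, regions)
    if d.size == 0:
        raise ValueError("no cis cells in the requested scope")
    lo, hi = d.min(), d.max()
    edges = np.geomspace(lo, hi * (1 + 1e-9), n_logbins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_logbins - 1)
    mean = np.full(n_logbins, np.nan)
    n_cells = np.zeros(n_logbins, dtype=int)
    for b in range(n_logbins):
        sel = which == b
        n_cells[b] = sel.sum()
        if n_cells[b]:
            mean[b] = vals[sel].mean()
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = n_cells > 0
    return ScalingCurve(centers[keep], mean[keep], n_cells[keep], scope)


def fit_scaling_slope(curve: ScalingCurve, d_min: float | None = None, d_max: float | None = None) -> float:
    """Log-log least-squares slope of a scaling curve over [d_min, d_max]."""
    d, m = curve.distance_bp, curve.mean
    keep = np.isfinite(m) & (m > 0)
    if d_min is not None:
        keep &= d >= d_min
    if d_max is not None:
        keep &= d <= d_max
    if keep.sum() < 3:
        raise ValueError("too few curve points to fit a slope")
    slope, _ = np.polyfit(np.log10(d[keep]), np.log10(m[keep]), 1)
    return float(slope)


def telomere_interaction(cmap: ContactMap, end_fraction: float = END_FRACTION) -> TelomereStats:
    """Mean intra-chromosomal contact between the two chromosome ends.

    Ends are the first and last ``end_fraction`` of each chromosome's
    length; chromosomes whose end regions span less than one bin are
    skipped with a warning.
    """
    if not 0 < end_fraction < 0.5:
        raise ValueError("end_fraction must be in (0, 0.5)")
    binning = cmap.binning
    v = cmap.masked_values()
    chroms, means = [], []
    for chrom in binning.chromosomes:
        s = binning.chrom_slice(chrom)
        nc = s.stop - s.start
        n_end = int(np.floor(end_fraction * nc))
        if n_end < 1:
            logger.warning("telomere_interaction: %s end region < 1 bin; skipped", chrom)
            continue
        block = v[s, s]
        cells = block[:n_end, nc - n_end:]
        if np.isfinite(cells).any():
            chroms.append(chrom)
            means.append(float(np.nanmean(cells)))
    return TelomereStats(chroms, np.array(means), end_fraction)


def compare_telomere(stats_a: TelomereStats, stats_b: TelomereStats) -> dict:
    """Rank-sum comparison of per-chromosome end-to-end means, plus ratios."""
    common = [c for c in stats_a.chromosomes if c in stats_b.chromosomes]
    if len(common) < 3:
        logger.warning("compare_telomere: only %d chromosomes; p unreliable", len(common))
    a = np.array([stats_a.means[stats_a.chromosomes.index(c)] for c in common])
    b = np.array([stats_b.means[stats_b.chromosomes.index(c)] for c in common])
    stat, p = rank_sum_test(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = a / b
    return {
        "chromosomes": common,
        "means_a": a,
        "means_b": b,
        "ratios": pd.Series(ratios, index=common),
        "statistic": stat,
        "p_value": p,
    }
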