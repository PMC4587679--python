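"""A/B compartment calling, switch classification and enrichment.

Compartments are read off the plaid pattern of the distance-normalized
contact map: per chromosome, the Pearson correlation matrix of cis z-score
columns is decomposed and the first principal component splits bins into
two mutually-interacting groups.  The eigenvector sign is arbitrary, so it
is oriented with gene density — the open, gene-rich A compartment gets
positive values, the closed, gene-poor B compartment negative.

Between two conditions each bin falls into one of four categories
(A->A, B->B stable; A->B, B->A switched); enrichment of switching on a
chromosome subset is tested with a Yates-corrected chi-square, and
expression changes are aggregated per switch category with rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBinning, GenomicIntervalSet
from .normalize import ZScoreMap
from .stats import rank_sum_test, yates_chi2

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentProfile",
    "SwitchTable",
    "call_compartments",
    "classify_switches",
    "switch_enrichment",
    "expression_by_switch",
]

MIN_BINS_PER_CHROM = 10
CATEGORIES = ("A->A", "B->B", "A->B", "B->A")


@dataclass
class CompartmentProfile:
    """Per-bin first-PC eigenvector, A/B labels, and orientation evidence.

    ``labels`` holds "A" (oriented eigenvector > 0), "B" (< 0) or "" where
    undefined.  ``orientation_evidence`` records, per chromosome, the
    Pearson correlation between the oriented eigenvector and gene density —
    low values flag chromosomes where the first component may not be the
    compartment signal.
    """

    binning: GenomeBinning
    eigenvector: np.ndarray
    labels: np.ndarray
    orientation_evidence: dict[str, float]


@dataclass
class SwitchTable:
    """Per-bin switch category between two conditions."""

    binning: GenomeBinning
    categories: np.ndarray  # strings from CATEGORIES or "" = undefined

    def counts(self, chroms: list[str] | None = None) -> dict[str, int]:
        cats = self.categories
        if chroms is not None:
            keep = np.zeros(len(cats), dtype=bool)
            for c in chroms:
                keep[self.binning.chrom_slice(c)] = True
            cats = cats[keep]
        return {c: int((cats == c).sum()) for c in CATEGORIES}


def call_compartments(z: ZScoreMap, genes: GenomicIntervalSet) -> CompartmentProfile:
    """First-PC compartment eigenvector per chromosome, gene-density oriented."""
    if len(genes) == 0:
        raise ValueError("gene interval set is empty (needed for A/B orientation)")
    binning = z.binning
    n = binning.n_bins
    evec = np.full(n, np.nan)
    labels = np.full(n, "", dtype=object)
    density = genes.midpoint_counts_per_bin(binning)
    evidence: dict[str, float] = {}

    for chrom in binning.chromosomes:
        s = binning.chrom_slice(chrom)
        block = z.values[s, s]
        defined = np.isfinite(block).sum(axis=0) > 0
        if defined.sum() < MIN_BINS_PER_CHROM:
            logger.warning("call_compartments: %s has %d defined bins (<%d); skipped",
                           chrom, int(defined.sum()), MIN_BINS_PER_CHROM)
            continue
        sub = block[np.ix_(defined, defined)]
        sub = np.where(np.isfinite(sub), sub, 0.0)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        w, v = np.linalg.eigh(corr)
        pc1 = v[:, -1]  # eigenvector of the largest eigenvalue

        dens = density[s][defined]
        rich = dens > np.median(dens)
        if rich.any() and pc1[rich].mean() < 0:
            pc1 = -pc1
        ev = np.full(s.stop - s.start, np.nan)
        ev[defined] = pc1
        evec[s] = ev
        lab = np.where(pc1 > 0, "A", np.where(pc1 < 0, "B", ""))
        full_lab = np.full(s.stop - s.start, "", dtype=object)
        full_lab[defined] = lab
        labels[s] = full_lab
        if np.std(dens) > 0 and np.std(pc1) > 0:
            evidence[chrom] = float(np.corrcoef(pc1, dens)[0, 1])
        else:
            evidence[chrom] = np.nan
    return CompartmentProfile(binning, evec, labels, evidence)


def classify_switches(p1: CompartmentProfile, p2: CompartmentProfile) -> SwitchTable:
    """Per-bin category from condition-1 and condition-2 labels."""
    if p1.binning != p2.binning:
        raise ValueError("compartment profiles do not share a binning")
    cats = np.full(p1.binning.n_bins, "", dtype=object)
    for i, (l1, l2) in enumerate(zip(p1.labels, p2.labels)):
        if l1 in ("A", "B") and l2 in ("A", "B"):
            cats[i] = f"{l1}->{l2}"
    return SwitchTable(p1.binning, cats)


def switch_enrichment(table: SwitchTable, subset: list[str]) -> dict[str, dict]:
    """Yates chi-square enrichment of each switch direction on a subset.

    For each direction (A->B, B->A) builds the 2x2 table
    (subset vs rest) x (switched-that-direction vs stable) and returns the
    continuity-corrected statistic, p value, and the table itself.
    """
    rest = [c for c in table.binning.chromosomes if c not in subset]
    in_counts = table.counts(subset)
    out_counts = table.counts(rest)
    stable_in = in_counts["A->A"] + in_counts["B->B"]
    stable_out = out_counts["A->A"] + out_counts["B->B"]
    results = {}
    for direction in ("A->B", "B->A"):
        tab = np.array([[in_counts[direction], stable_in],
                        [out_counts[direction], stable_out]], dtype=float)
        row = tab.sum(axis=1, keepdims=True)
        col = tab.sum(axis=0, keepdims=True)
        expected = row @ col / tab.sum()
        if (expected < 1).any():
            logger.warning("switch_enrichment: expected cell < 1 for %s", direction)
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            # no switches of this direction anywhere: no evidence of enrichment
            stat, p = 0.0, 1.0
        else:
            stat, p = yates_chi2(tab)
        results[direction] = {"table": tab, "chi2": stat, "p_value": p}
    return results


def expression_by_switch(table: SwitchTable, expr: pd.DataFrame) -> dict:
    """Aggregate gene expression changes by the switch category of the bin
    containing each gene's midpoint.

    ``expr`` needs columns chrom, start, end, log2fc.  Returns per-category
    value lists and medians plus rank-sum p values of each switch direction
    against the pooled stable categories.
    """
    binning = table.binning
    values: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    skipped = 0
    for row in expr.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        if row.chrom not in binning.chromosomes or not 0 <= mid < binning.chrom_lengths[row.chrom]:
            skipped += 1
            continue
        cat = table.categories[binning.bin_index(row.chrom, mid)]
        if cat:
            values[cat].append(float(row.log2fc))
    if skipped:
        logger.warning("expression_by_switch: %d genes outside the binning skipped", skipped)
    stable = values["A->A"] + values["B->B"]
    out = {
        "values": values,
        "medians": {c: (float(np.median(v)) if v else np.nan) for c, v in values.items()},
        "n_skipped": skipped,
    }
    for direction in ("A->B", "B->A"):
        if values[direction] and stable:
            _, p = rank_sum_test(values[direction], stable)
        else:
            p = np.nan
        out[f"p_{direction}_vs_stable"] = p
    return out
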