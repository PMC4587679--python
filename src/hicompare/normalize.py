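"""Matrix balancing and distance-normalized z-score transform.

Two stages turn raw binned counts into a statistic comparable across
samples and distances:

1. **ICE balancing** — symmetric alternating (Sinkhorn-style) scaling that
   equalizes unmasked bin marginals, absorbing coverage and copy-number
   biases into a per-bin factor ``b_i``; corrected values are
   ``values[i,j] / (b_i * b_j)``, rescaled to preserve the total count.
   Dividing by the matrix total then yields the relative (sum-normalized)
   form in which copy-number differences between samples cancel.

2. **Distance z-scores** — for every genomic separation ``d`` the unmasked
   cis values are pooled, trimmed by an interquartile-range rule, and
   summarized by a mean and sample SD; the two per-distance curves are then
   smoothed over distance by locally weighted regression (lowess) of span
   ``alpha``.  Each cis cell becomes ``z = (value - mean(d)) / sd(d)``,
   removing the dominant distance-decay signal.  Trans cells are
   standardized against the pooled mean/SD of all unmasked trans values,
   so pair-level contact differences survive into the z-map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import ContactMap, GenomeBinning

logger = logging.getLogger(__name__)

__all__ = [
    "BiasVector",
    "ExpectedProfile",
    "ZScoreMap",
    "ice_balance",
    "distance_expected",
    "zscore_transform",
]

ICE_TOL = 1e-5
ICE_MAX_ITER = 200
LOWESS_ALPHA = 0.01  # smoothing span for the per-distance expected curves
IQR_FACTOR = 1.5


@dataclass
class BiasVector:
    """Per-bin multiplicative bias; NaN on masked bins."""

    values: np.ndarray
    converged: bool
    n_iter: int
    final_cv: float


@dataclass
class ExpectedProfile:
    """Smoothed per-distance mean and SD of cis contacts.

    ``distances`` are in bins; ``mean``/``sd`` are NaN where fewer than two
    values survived the IQR filter.  ``scope`` is "genome" or a chromosome
    name when profiles are computed per chromosome.
    """

    distances: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_used: np.ndarray
    alpha: float
    iqr_factor: float
    scope: str = "genome"

    def lookup(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = np.full(d.shape, np.nan)
        sd = np.full(d.shape, np.nan)
        valid = (d >= 1) & (d <= self.distances[-1]) if self.distances.size else np.zeros(d.shape, bool)
        idx = np.clip(d - 1, 0, max(len(self.distances) - 1, 0))
        mean[valid] = self.mean[idx[valid]]
        sd[valid] = self.sd[idx[valid]]
        return mean, sd


@dataclass
class ZScoreMap:
    """Distance-normalized symmetric matrix; NaN where undefined."""

    binning: GenomeBinning
    values: np.ndarray
    profile: ExpectedProfile | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.binning.n_bins
        if self.values.shape != (n, n):
            raise ValueError("z-score matrix shape mismatch")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def ice_balance(
    cmap: ContactMap,
    tol: float = ICE_TOL,
    max_iter: int = ICE_MAX_ITER,
) -> tuple[ContactMap, BiasVector]:
    """Balance a raw contact map so all unmasked marginals are equal.

    Iteratively divides rows and columns by their marginal relative to the
    mean marginal until the coefficient of variation of unmasked marginals
    drops below ``tol``.  The corrected matrix keeps the input's total
    count; divide by :meth:`ContactMap.total` for the relative form.

    Returns the balanced map (state="ice") and the bias vector.  Bins whose
    marginal is zero are masked before balancing.
    """
    if cmap.state != "raw":
        logger.warning("ice_balance called on state=%r map", cmap.state)
    mask = cmap.mask.copy()
    values = cmap.values.copy()
    marginals = values[~mask][:, ~mask].sum(axis=0) if (~mask).any() else np.array([])
    zero = np.zeros_like(mask)
    zero[~mask] = marginals == 0
    if zero.any():
        logger.warning("ice_balance: masking %d zero-marginal bins", int(zero.sum()))
        mask = mask | zero
    active = ~mask
    if active.sum() < 2:
        raise ValueError("fewer than 2 unmasked bins")

    sub = values[np.ix_(active, active)]
    bias = np.ones(active.sum())
    cv = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        corrected = sub / np.outer(bias, bias)
        m = corrected.sum(axis=0)
        mean_m = m.mean()
        cv = m.std() / mean_m
        if cv <= tol:
            break
        bias *= np.sqrt(m / mean_m)
    converged = cv <= tol
    if not converged:
        logger.warning("ice_balance: no convergence in %d iterations (CV=%.3g)", max_iter, cv)

    corrected = sub / np.outer(bias, bias)
    corrected *= sub.sum() / corrected.sum()  # preserve total mass

    out_values = np.zeros_like(values)
    out_values[np.ix_(active, active)] = corrected
    full_bias = np.full(values.shape[0], np.nan)
    full_bias[active] = bias / np.exp(np.mean(np.log(bias)))  # geometric mean 1
    out = ContactMap(cmap.binning, out_values, mask=mask, state="ice")
    return out, BiasVector(full_bias, converged, n_iter, float(cv))


def _per_distance_stats(values_by_distance, iqr_factor: float):
    """IQR-filtered mean, sample SD and count for one distance's pool."""
    v = np.asarray(values_by_distance, dtype=float)
    v = v[np.isfinite(v)]
    if v.size >= 4 and iqr_factor is not None:
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        keep = (v >= q1 - iqr_factor * iqr) & (v <= q3 + iqr_factor * iqr)
        v = v[keep]
    if v.size < 2:
        return np.nan, np.nan, v.size
    return float(v.mean()), float(v.std(ddof=1)), v.size


def distance_expected(
    cmap: ContactMap,
    alpha: float = LOWESS_ALPHA,
    iqr_factor: float | None = IQR_FACTOR,
    scope: str = "genome",
) -> ExpectedProfile | dict[str, ExpectedProfile]:
    """Per-distance expected mean/SD of cis contacts, lowess-smoothed.

    ``alpha`` is the lowess span as a proportion of the distance range;
    ``alpha = 0`` disables smoothing (each distance keeps its own raw mean
    and SD).  ``iqr_factor = None`` disables the outlier filter.  With
    ``scope="per-chromosome"`` a profile is returned per chromosome.
    """
    binning = cmap.binning
    if scope == "per-chromosome":
        return {
            c: _distance_expected_single(cmap, [c], alpha, iqr_factor, scope=c)
            for c in binning.chromosomes
        }
    return _distance_expected_single(cmap, list(binning.chromosomes), alpha, iqr_factor, scope="genome")


def _distance_expected_single(cmap, chroms, alpha, iqr_factor, scope) -> ExpectedProfile:
    v = cmap.masked_values()
    binning = cmap.binning
    max_d = max(binning.chrom_nbins(c) for c in chroms) - 1
    pools: dict[int, list] = {d: [] for d in range(1, max_d + 1)}
    for chrom in chroms:
        s = binning.chrom_slice(chrom)
        block = v[s, s]
        nc = block.shape[0]
        for d in range(1, nc):
            pools[d].append(np.diagonal(block, offset=d))
    distances = np.arange(1, max_d + 1)
    mean = np.full(max_d, np.nan)
    sd = np.full(max_d, np.nan)
    n_used = np.zeros(max_d, dtype=int)
    for d in distances:
        if pools[d]:
            mean[d - 1], sd[d - 1], n_used[d - 1] = _per_distance_stats(
                np.concatenate(pools[d]), iqr_factor
            )
    if alpha and alpha > 0:
        # smooth in log-log coordinates: power-law decay is locally linear
        # there, so the local regression is unbiased for the dominant trend
        for curve in (mean, sd):
            ok = np.isfinite(curve) & (curve > 0)
            if ok.sum() >= 3:
                frac = max(alpha, 3 / ok.sum())
                x = np.log(distances[ok].astype(float))
                sm = lowess(np.log(curve[ok]), x, frac=frac, return_sorted=False)
                curve[ok] = np.exp(sm)
    return ExpectedProfile(distances, mean, sd, n_used, alpha=alpha or 0.0,
                           iqr_factor=iqr_factor if iqr_factor is not None else np.nan,
                           scope=scope)


def zscore_transform(cmap: ContactMap, profile) -> ZScoreMap:
    """Standardize a balanced map against its distance-expected profile.

    Cis: ``z(i,j) = (value - mean(|i-j|)) / sd(|i-j|)``; NaN on the
    diagonal, masked bins, and distances where the profile is undefined or
    has zero SD.  Trans: standardized against the pooled mean and sample SD
    of all unmasked trans cells, so chromosome-pair-level contact
    differences (translocations, subset-wide trans shifts) survive into the
    z-map instead of being absorbed pair by pair.  ``profile`` is a
    genome-wide :class:`ExpectedProfile` or a per-chromosome dict of them.
    """
    binning = cmap.binning
    v = cmap.masked_values()
    z = np.full(v.shape, np.nan)
    for chrom in binning.chromosomes:
        s = binning.chrom_slice(chrom)
        block = v[s, s]
        nc = block.shape[0]
        prof = profile[chrom] if isinstance(profile, dict) else profile
        idx = np.arange(nc)
        d = np.abs(idx[:, None] - idx[None, :])
        mean, sd = prof.lookup(d)
        with np.errstate(invalid="ignore", divide="ignore"):
            zb = (block - mean) / np.where(sd > 0, sd, np.nan)
        zb[d == 0] = np.nan
        z[s, s] = zb
    chrom_of = binning.bin_chrom_index()
    trans = chrom_of[:, None] != chrom_of[None, :]
    vals = v[trans]
    vals = vals[np.isfinite(vals)]
    if vals.size >= 2 and vals.std(ddof=1) > 0:
        z[trans] = (v[trans] - vals.mean()) / vals.std(ddof=1)
    return ZScoreMap(binning, z, profile=profile if not isinstance(profile, dict) else None)
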