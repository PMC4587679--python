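"""Genome coordinate system and contact-map containers.

Everything downstream shares one coordinate system: a fixed-width tiling of
an ordered chromosome set (:class:`GenomeBinning`), symmetric binned contact
matrices on that tiling (:class:`ContactMap`), and plain interval sets for
annotations (:class:`GenomicIntervalSet`).

Conventions
-----------
* Bins and intervals are 0-based, half-open ``[start, end)`` internally,
  matching BED on disk.
* Valid-pairs positions are read as 1-based (the common pairs-file
  convention) and converted on ingestion.
* Masked bins are excluded from statistics as *missing* values, never
  counted as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeBinning",
    "GenomicIntervalSet",
    "ContactMap",
    "make_binning",
    "bin_pairs",
    "mask_low_coverage",
]


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width tiling of a chromosome set.

    Bins tile each chromosome exactly: they start at 0, are consecutive and
    non-overlapping, and the final (possibly shorter) bin ends at the
    chromosome length.  Global bin ordinals run 0..N-1 in chromosome order.
    """

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int
    # per-chromosome global offset of the first bin
    _offsets: tuple[int, ...] = field(repr=False, default=())
    _nbins: tuple[int, ...] = field(repr=False, default=())

    @property
    def n_bins(self) -> int:
        return int(sum(self._nbins))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.chromosomes, self.lengths))

    def chrom_nbins(self, chrom: str) -> int:
        return self._nbins[self.chromosomes.index(chrom)]

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[self.chromosomes.index(chrom)]

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of global bin ordinals belonging to one chromosome."""
        i = self.chromosomes.index(chrom)
        return slice(self._offsets[i], self._offsets[i] + self._nbins[i])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global ordinal of the bin containing a 0-based position."""
        i = self.chromosomes.index(chrom)
        if not 0 <= pos < self.lengths[i]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.lengths[i]})")
        return self._offsets[i] + pos // self.bin_size

    def bins(self) -> pd.DataFrame:
        """All bins as a DataFrame with columns chrom, start, end."""
        rows = []
        for chrom, length in zip(self.chromosomes, self.lengths):
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_labels(self) -> list[str]:
        b = self.bins()
        return [f"{c}:{s}-{e}" for c, s, e in zip(b["chrom"], b["start"], b["end"])]

    def bin_chrom_index(self) -> np.ndarray:
        """Per global bin, the ordinal of its chromosome."""
        return np.repeat(np.arange(len(self.chromosomes)), self._nbins)

    def __eq__(self, other) -> bool:  # offsets are derived, compare the basis
        if not isinstance(other, GenomeBinning):
            return NotImplemented
        return (
            self.chromosomes == other.chromosomes
            and self.lengths == other.lengths
            and self.bin_size == other.bin_size
        )

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.lengths, self.bin_size))


def make_binning(chrom_sizes, bin_size: int) -> GenomeBinning:
    """Tile a chromosome-size table into non-overlapping fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Mapping of chromosome name to length in bp, or an iterable of
        (name, length) pairs; order is preserved.
    bin_size
        Bin width in bp; the last bin of each chromosome may be shorter.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    items = list(chrom_sizes.items()) if hasattr(chrom_sizes, "items") else list(chrom_sizes)
    names = [str(n) for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    lengths = []
    for name, length in items:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length {length}")
        lengths.append(length)
    nbins = [-(-l // bin_size) for l in lengths]  # ceil division
    offsets = np.concatenate([[0], np.cumsum(nbins)[:-1]]).astype(int)
    return GenomeBinning(
        chromosomes=tuple(names),
        lengths=tuple(lengths),
        bin_size=int(bin_size),
        _offsets=tuple(int(o) for o in offsets),
        _nbins=tuple(int(n) for n in nbins),
    )


@dataclass
class GenomicIntervalSet:
    """A set of genomic intervals with optional name/score, BED-like.

    Stored as a DataFrame with columns chrom, start, end and optionally
    name, score.  Coordinates are 0-based half-open.
    """

    records: pd.DataFrame

    REQUIRED = ("chrom", "start", "end")

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"interval set missing column {col!r}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[~(df["start"] < df["end"])][0]
            raise ValueError(f"interval with start >= end at record {bad}")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative interval start")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def sort(self, binning: GenomeBinning | None = None) -> "GenomicIntervalSet":
        """Sort by (chromosome order, start); binning supplies the order."""
        df = self.records.copy()
        if binning is not None:
            order = {c: i for i, c in enumerate(binning.chromosomes)}
            df["_c"] = df["chrom"].map(order)
        else:
            df["_c"] = df["chrom"]
        df = df.sort_values(["_c", "start"]).drop(columns="_c").reset_index(drop=True)
        return GenomicIntervalSet(df)

    def subset(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom]

    def midpoints(self) -> pd.DataFrame:
        df = self.records
        return pd.DataFrame({"chrom": df["chrom"], "pos": (df["start"] + df["end"]) // 2})

    def midpoint_counts_per_bin(self, binning: GenomeBinning) -> np.ndarray:
        """Number of interval midpoints falling in each bin (density proxy)."""
        counts = np.zeros(binning.n_bins)
        for chrom, pos in self.midpoints().itertuples(index=False):
            if chrom in binning.chromosomes and 0 <= pos < binning.chrom_lengths[chrom]:
                counts[binning.bin_index(chrom, int(pos))] += 1
        return counts


@dataclass
class ContactMap:
    """Symmetric binned genome-wide interaction matrix.

    ``values`` is dense N x N; ``mask`` marks excluded bins (True = masked).
    ``state`` tracks the processing stage: ``raw`` counts, ``ice`` balanced,
    or ``expected`` intensities.  Masked bins are treated as missing in all
    statistics, never as zeros.
    """

    binning: GenomeBinning
    values: np.ndarray
    mask: np.ndarray = None
    state: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.binning.n_bins
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(self.values) < 0:
            raise ValueError("contact values must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length mismatch")

    def masked_values(self) -> np.ndarray:
        """Copy of values with masked rows/columns set to NaN."""
        out = self.values.copy()
        out[self.mask, :] = np.nan
        out[:, self.mask] = np.nan
        return out

    def cis_block(self, chrom: str) -> np.ndarray:
        s = self.binning.chrom_slice(chrom)
        return self.values[s, s]

    def trans_block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        return self.values[self.binning.chrom_slice(chrom_a), self.binning.chrom_slice(chrom_b)]

    def total(self) -> float:
        """Total pair mass: upper triangle plus diagonal, unmasked bins."""
        v = self.masked_values()
        iu = np.triu_indices(v.shape[0])
        return float(np.nansum(v[iu]))

    def copy(self) -> "ContactMap":
        return ContactMap(self.binning, self.values.copy(), self.mask.copy(), self.state)


def bin_pairs(pairs, binning: GenomeBinning) -> ContactMap:
    """Aggregate a stream of valid pairs into a raw contact matrix.

    Each pair is (chromA, posA, chromB, posB) with 1-based positions.  Every
    pair increments cell (binA, binB) and its mirror; self-pairs hit the
    diagonal once.  Pairs with positions outside their chromosome are
    rejected with a logged count.
    """
    n = binning.n_bins
    values = np.zeros((n, n))
    rejected = 0
    lengths = binning.chrom_lengths
    length_arr = np.array(binning.lengths)
    offset_arr = np.array(binning._offsets)
    chrom_ord = {c: i for i, c in enumerate(binning.chromosomes)}

    def flush(ca, pa, cb, pb):
        nonlocal rejected
        ca = np.array(ca)
        cb = np.array(cb)
        pa = np.asarray(pa, dtype=np.int64) - 1  # 1-based -> 0-based
        pb = np.asarray(pb, dtype=np.int64) - 1
        ok = (pa >= 0) & (pa < length_arr[ca]) & (pb >= 0) & (pb < length_arr[cb])
        rejected += int((~ok).sum())
        i = offset_arr[ca[ok]] + pa[ok] // binning.bin_size
        j = offset_arr[cb[ok]] + pb[ok] // binning.bin_size
        np.add.at(values, (i, j), 1)
        off = i != j
        np.add.at(values, (j[off], i[off]), 1)

    if isinstance(pairs, pd.DataFrame):  # vectorized fast path
        ca = pairs.iloc[:, 0].map(chrom_ord)
        cb = pairs.iloc[:, 2].map(chrom_ord)
        if ca.isna().any() or cb.isna().any():
            raise ValueError("unknown chromosome in pairs table")
        flush(ca.to_numpy(int), pairs.iloc[:, 1].to_numpy(), cb.to_numpy(int), pairs.iloc[:, 3].to_numpy())
        if rejected:
            logger.warning("bin_pairs: rejected %d pairs with out-of-range positions", rejected)
        return ContactMap(binning, values, state="raw")

    buf_ca, buf_pa, buf_cb, buf_pb = [], [], [], []
    for chrom_a, pos_a, chrom_b, pos_b in pairs:
        if chrom_a not in lengths or chrom_b not in lengths:
            raise ValueError(f"unknown chromosome in pair ({chrom_a}, {chrom_b})")
        buf_ca.append(chrom_ord[chrom_a])
        buf_pa.append(int(pos_a))
        buf_cb.append(chrom_ord[chrom_b])
        buf_pb.append(int(pos_b))
        if len(buf_ca) == 1_000_000:
            flush(buf_ca, buf_pa, buf_cb, buf_pb)
            buf_ca, buf_pa, buf_cb, buf_pb = [], [], [], []
    if buf_ca:
        flush(buf_ca, buf_pa, buf_cb, buf_pb)
    if rejected:
        logger.warning("bin_pairs: rejected %d pairs with out-of-range positions", rejected)
    return ContactMap(binning, values, state="raw")


def mask_low_coverage(cmap: ContactMap, fraction: float = 0.0) -> ContactMap:
    """Mask zero-marginal bins and the lowest-covered fraction of the rest.

    Bins whose marginal (row sum) is zero are always masked; additionally
    the lowest ``fraction`` of nonzero-marginal bins are masked.  Values are
    untouched; only the mask is updated.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    marginals = cmap.values.sum(axis=0)
    mask = cmap.mask | (marginals == 0)
    nonzero = np.where(~mask)[0]
    k = int(np.floor(fraction * len(nonzero)))
    if k > 0:
        order = nonzero[np.argsort(marginals[nonzero], kind="stable")]
        mask[order[:k]] = True
    out = cmap.copy()
    out.mask = mask
    return out
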