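"""Readers and writers for the plain-text interchange formats.

Formats
-------
* chromosome sizes: two-column TSV ``name<TAB>length``
* valid pairs: four-column TSV ``chromA posA chromB posB`` (1-based
  positions), optional header, ``#`` comments ignored
* dense matrix: TSV with ``chrom:start-end`` bin labels as row and column
  headers; masked bins written as ``nan``
* triplet matrix: ``binA_label binB_label value``; the upper triangle is
  sufficient, symmetry is reconstructed on read
* BED 3/5-column and bedGraph 4-column for interval sets and tracks
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .genome import ContactMap, GenomeBinning, GenomicIntervalSet, make_binning

__all__ = [
    "read_chrom_sizes",
    "read_pairs",
    "write_pairs",
    "write_dense",
    "read_dense",
    "write_triplet",
    "read_triplet",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]

_LABEL_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_pairs(path):
    """Yield (chromA, posA, chromB, posB) valid-pair tuples from a TSV."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chroma", "chrom_a", "chrom1"):
                continue  # header
            ca, pa, cb, pb = fields[:4]
            yield ca, int(pa), cb, int(pb)


def read_pairs_df(path) -> pd.DataFrame:
    """Whole valid-pairs file as a DataFrame (fast path for binning)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chromA", "posA", "chromB", "posB"],
                     dtype={"chromA": str, "chromB": str})
    if len(df) and not np.issubdtype(df["posA"].dtype, np.number):  # header row
        df = df.iloc[1:].astype({"posA": int, "posB": int})
    return df


def write_pairs(path, pairs) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("#chromA\tposA\tchromB\tposB\n")
        for ca, pa, cb, pb in pairs:
            fh.write(f"{ca}\t{pa}\t{cb}\t{pb}\n")
            n += 1
    return n


def _parse_labels(labels) -> tuple[list[tuple[str, int, int]], GenomeBinning]:
    parsed = []
    for lab in labels:
        m = _LABEL_RE.match(lab)
        if m is None:
            raise ValueError(f"malformed bin label {lab!r}")
        parsed.append((m.group(1), int(m.group(2)), int(m.group(3))))
    sizes: dict[str, int] = {}
    widths = set()
    for chrom, start, end in parsed:
        sizes[chrom] = max(sizes.get(chrom, 0), end)
        widths.add(end - start)
    bin_size = max(widths)
    binning = make_binning(sizes, bin_size)
    expected = [tuple(r) for r in binning.bins().itertuples(index=False)]
    if parsed != expected:
        first = next(i for i, (a, b) in enumerate(zip(parsed, expected)) if a != b)
        raise ValueError(f"bin labels do not tile the genome; first mismatch at record {first}: {parsed[first]}")
    return parsed, binning


def write_dense(path, cmap: ContactMap) -> None:
    labels = cmap.binning.bin_labels()
    df = pd.DataFrame(cmap.masked_values(), index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="nan")


def read_dense(path, state: str = "raw") -> ContactMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("dense matrix row and column labels differ")
    _, binning = _parse_labels(list(df.index))
    values = df.to_numpy(dtype=float)
    # a fully-NaN row marks a masked bin
    mask = np.all(np.isnan(values), axis=0)
    values = np.nan_to_num(values, nan=0.0)
    return ContactMap(binning, values, mask=mask, state=state)


def write_triplet(path, cmap: ContactMap) -> None:
    """Write nonzero upper-triangle cells of unmasked bins as triplets."""
    labels = cmap.binning.bin_labels()
    v = cmap.masked_values()
    with open(path, "w") as fh:
        fh.write(f"#bins\t{cmap.binning.n_bins}\n")
        for lab, m in zip(labels, cmap.mask):
            if m:
                fh.write(f"#masked\t{lab}\n")
        i_idx, j_idx = np.nonzero(np.triu(np.nan_to_num(v, nan=0.0)))
        for i, j in zip(i_idx, j_idx):
            fh.write(f"{labels[i]}\t{labels[j]}\t{v[i, j]:.10g}\n")


def read_triplet(path, binning: GenomeBinning, state: str = "raw") -> ContactMap:
    """Rebuild a symmetric matrix from (possibly upper-triangle-only) triplets."""
    n = binning.n_bins
    labels = {lab: i for i, lab in enumerate(binning.bin_labels())}
    values = np.zeros((n, n))
    mask = np.zeros(n, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line.split("\t")
                if fields[0] == "#masked" and len(fields) > 1:
                    if fields[1] not in labels:
                        raise ValueError(f"line {lineno}: masked label {fields[1]!r} not in binning")
                    mask[labels[fields[1]]] = True
                continue
            la, lb, val = line.split("\t")
            if la not in labels or lb not in labels:
                raise ValueError(f"line {lineno}: bin label not in binning: {la!r} / {lb!r}")
            i, j = labels[la], labels[lb]
            values[i, j] = float(val)
            values[j, i] = float(val)
    return ContactMap(binning, values, mask=mask, state=state)


def read_bed(path) -> GenomicIntervalSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED record needs >= 3 fields")
            rec = {"chrom": fields[0], "start": int(fields[1]), "end": int(fields[2])}
            if int(fields[1]) >= int(fields[2]):
                raise ValueError(f"line {lineno}: start >= end")
            if len(fields) >= 4:
                rec["name"] = fields[3]
            if len(fields) >= 5:
                rec["score"] = float(fields[4])
            rows.append(rec)
    cols = ["chrom", "start", "end"] + [c for c in ("name", "score") if rows and c in rows[0]]
    return GenomicIntervalSet(pd.DataFrame(rows, columns=cols if rows else ["chrom", "start", "end"]))


def write_bed(path, intervals: GenomicIntervalSet) -> None:
    df = intervals.records
    cols = ["chrom", "start", "end"] + [c for c in ("name", "score") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path, binning: GenomeBinning, track: np.ndarray) -> None:
    """Write a per-bin real-valued track; NaN bins are skipped."""
    bins = binning.bins()
    with open(path, "w") as fh:
        for (chrom, start, end), val in zip(bins.itertuples(index=False), track):
            if np.isfinite(val):
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")
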