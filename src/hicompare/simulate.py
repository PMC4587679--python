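"""Synthetic Hi-C generator with planted, recoverable structure.

The generator builds an *expected* contact-intensity matrix from explicit
multiplicative components — power-law distance decay, plaid A/B compartment
structure, TAD blocks, inter-chromosomal translocation blocks, a
trans-contact multiplier for a named chromosome subset, telomere end-to-end
boosts, per-bin coverage biases and per-chromosome copy-number factors —
then draws Poisson counts around it.  Because every component is planted
explicitly, every downstream stage (balancing, z-scores, differential
scores, compartment calls, boundary calls, scaling curves) can be scored
against known truth.

Cis expectation for bins i, j of the same chromosome::

    E[i,j] = d(i,j)^(-decay_exponent)
             * (1 + compartment_strength * e_i * e_j)
             * tad_factor(i,j) * telomere_factor(i,j)

with ``d`` the genomic separation in bp.  ``tad_factor`` is
``tad_strength`` when i and j lie between the same adjacent planted
boundaries, else 1; ``telomere_factor`` is ``telomere_boost`` when i is in
the first and j in the last ``end_fraction`` of the chromosome.  Trans
expectation is a flat ``trans_floor`` times translocation-block and
small-chromosome-subset factors.  The whole matrix is then multiplied by
``bias_i * bias_j`` and the chromosome copy-number factors and scaled so the
expected total pair count equals ``depth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import ContactMap, GenomeBinning, GenomicIntervalSet, make_binning

__all__ = [
    "SyntheticSpec",
    "expected_map",
    "sample_map",
    "block_compartment_profile",
    "even_tad_boundaries",
    "two_condition_scenario",
]


@dataclass
class SyntheticSpec:
    """Full parameterization of the planted-truth generator.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping name -> length (bp).
    bin_size
        Bin width in bp.
    decay_exponent
        Power-law exponent of cis contact decay with distance (typical
        Hi-C values 0.8-1.5; default 1.0, the fractal-globule slope).
    trans_floor
        Baseline inter-chromosomal intensity relative to the cis decay
        curve's bp-distance scale.
    compartment_profile
        Per-bin vector in [-1, 1] (the planted eigenvector); None disables
        compartments.
    compartment_strength
        Plaid amplitude: cell factor is 1 + strength * e_i * e_j.
    tad_boundaries
        Mapping chromosome -> list of boundary bin ordinals (chromosome-
        local, strictly inside); None disables TADs.
    tad_strength
        Within-TAD vs between-TAD contact ratio.
    translocations
        List of (chromA, chromB, (startA, endA, startB, endB) bin ranges,
        intensity multiplier) planted trans blocks.
    small_chrom_trans_factor
        (chromosome subset, multiplier) applied to trans contacts where
        both chromosomes are in the subset; None disables.
    telomere_boost
        Multiplier on end-to-end cis contacts (1 = no clustering).
    end_fraction
        Chromosome-length proportion defining the "ends" (default 0.05,
        i.e. the terminal 5% at each side).
    bias
        Per-bin positive multiplier (coverage/mappability bias); None = 1.
    copy_number
        Mapping chromosome -> positive multiplier; None = 1.
    depth
        Expected total read pairs.
    seed
        Base seed; replicate draws combine it with a replicate seed.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    decay_exponent: float = 1.0
    trans_floor: float = 1e-3
    compartment_profile: np.ndarray | None = None
    compartment_strength: float = 0.0
    tad_boundaries: dict[str, list[int]] | None = None
    tad_strength: float = 1.0
    translocations: list[tuple] = field(default_factory=list)
    small_chrom_trans_factor: tuple[list[str], float] | None = None
    telomere_boost: float = 1.0
    end_fraction: float = 0.05
    bias: np.ndarray | None = None
    copy_number: dict[str, float] | None = None
    depth: float = 1e6
    seed: int = 0

    def binning(self) -> GenomeBinning:
        return make_binning(self.chrom_sizes, self.bin_size)

    def validate(self) -> None:
        if not 0 < self.end_fraction < 0.5:
            raise ValueError("end_fraction must be in (0, 0.5)")
        for mult, name in [(self.tad_strength, "tad_strength"), (self.telomere_boost, "telomere_boost"), (self.trans_floor, "trans_floor")]:
            if mult <= 0:
                raise ValueError(f"{name} must be positive")
        binning = self.binning()
        if self.tad_boundaries:
            for chrom, bounds in self.tad_boundaries.items():
                n = binning.chrom_nbins(chrom)
                if any(not 0 < b < n for b in bounds):
                    raise ValueError(f"TAD boundary outside chromosome {chrom}")
        if self.bias is not None and (np.asarray(self.bias) <= 0).any():
            raise ValueError("bias multipliers must be positive")

    def truth_boundaries(self) -> GenomicIntervalSet:
        """Planted TAD boundaries as one-bin BED intervals."""
        import pandas as pd

        rows = []
        for chrom, bounds in (self.tad_boundaries or {}).items():
            for b in bounds:
                rows.append({"chrom": chrom, "start": b * self.bin_size, "end": (b + 1) * self.bin_size})
        return GenomicIntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def block_compartment_profile(binning: GenomeBinning, block_bins: int = 10, amplitude: float = 0.8, rng=None) -> np.ndarray:
    """Alternating-sign block eigenvector, the classic plaid pattern.

    Blocks of ``block_bins`` bins alternate between +amplitude and
    -amplitude; per-bin jitter (if an rng is given) keeps magnitudes in
    [-1, 1] while preserving block signs.
    """
    e = np.empty(binning.n_bins)
    for chrom in binning.chromosomes:
        s = binning.chrom_slice(chrom)
        n = s.stop - s.start
        signs = np.repeat([1.0, -1.0], block_bins)
        reps = -(-n // (2 * block_bins))
        e[s] = np.tile(signs, reps)[:n] * amplitude
    if rng is not None:
        jitter = rng.uniform(0.75, 1.0, size=e.size)
        e = e * jitter
    return e


def even_tad_boundaries(binning: GenomeBinning, spacing_bins: int) -> dict[str, list[int]]:
    """Boundaries every ``spacing_bins`` bins, strictly inside each chromosome."""
    out = {}
    for chrom in binning.chromosomes:
        n = binning.chrom_nbins(chrom)
        out[chrom] = [b for b in range(spacing_bins, n, spacing_bins) if b < n - 1]
    return out


def _tad_membership(n: int, boundaries: list[int]) -> np.ndarray:
    """Label each bin with the index of the TAD it belongs to."""
    labels = np.zeros(n, dtype=int)
    for k, b in enumerate(sorted(boundaries), start=1):
        labels[b:] = k
    return labels


def expected_map(spec: SyntheticSpec) -> ContactMap:
    """Deterministic expected-intensity matrix implied by a spec."""
    spec.validate()
    binning = spec.binning()
    n = binning.n_bins
    values = np.zeros((n, n))

    # cis: decay x compartments x TADs x telomeres
    for chrom in binning.chromosomes:
        s = binning.chrom_slice(chrom)
        nc = s.stop - s.start
        idx = np.arange(nc)
        dist_bins = np.abs(idx[:, None] - idx[None, :])
        # diagonal expectation pinned to the distance-one value (the
        # diagonal is excluded from every analysis anyway)
        d = np.maximum(dist_bins, 1) * float(spec.bin_size)
        block = d ** (-spec.decay_exponent)
        if spec.compartment_profile is not None and spec.compartment_strength != 0:
            e = np.asarray(spec.compartment_profile)[s]
            plaid = 1.0 + spec.compartment_strength * np.outer(e, e)
            block = block * np.clip(plaid, 1e-6, None)
        if spec.tad_boundaries and chrom in spec.tad_boundaries and spec.tad_strength != 1.0:
            labels = _tad_membership(nc, spec.tad_boundaries[chrom])
            same = labels[:, None] == labels[None, :]
            block = block * np.where(same, spec.tad_strength, 1.0)
        if spec.telomere_boost != 1.0:
            n_end = max(1, int(np.floor(spec.end_fraction * nc)))
            if 2 * n_end <= nc:
                telo = np.ones((nc, nc))
                telo[:n_end, nc - n_end:] = spec.telomere_boost
                telo[nc - n_end:, :n_end] = spec.telomere_boost
                block = block * telo
        values[s, s] = block

    # trans: flat floor x translocations x small-chromosome factor
    chrom_of = binning.bin_chrom_index()
    trans_cell = spec.trans_floor * (1.0 * spec.bin_size) ** (-spec.decay_exponent)
    trans = chrom_of[:, None] != chrom_of[None, :]
    values[trans] = trans_cell
    if spec.small_chrom_trans_factor is not None:
        subset, factor = spec.small_chrom_trans_factor
        in_subset = np.isin(chrom_of, [binning.chromosomes.index(c) for c in subset])
        both = np.outer(in_subset, in_subset) & trans
        values[both] *= factor
    for chrom_a, chrom_b, (sa, ea, sb, eb), intensity in spec.translocations:
        off_a = binning.chrom_offset(chrom_a)
        off_b = binning.chrom_offset(chrom_b)
        values[off_a + sa:off_a + ea, off_b + sb:off_b + eb] *= intensity
        values[off_b + sb:off_b + eb, off_a + sa:off_a + ea] *= intensity

    # per-bin bias and per-chromosome copy number
    scale = np.ones(n)
    if spec.bias is not None:
        scale = scale * np.asarray(spec.bias, dtype=float)
    if spec.copy_number:
        cn = np.array([spec.copy_number.get(c, 1.0) for c in binning.chromosomes])
        scale = scale * cn[chrom_of]
    values = values * np.outer(scale, scale)

    # normalize the expected total pair count (upper triangle + diagonal)
    total = np.triu(values).sum()
    values = values * (spec.depth / total)
    return ContactMap(binning, values, state="expected")


def sample_map(spec: SyntheticSpec, replicate_seed: int = 0) -> ContactMap:
    """Poisson count draw around the expected map; deterministic per seed."""
    exp = expected_map(spec)
    rng = np.random.default_rng([spec.seed, replicate_seed])
    n = exp.values.shape[0]
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[iu] = rng.poisson(exp.values[iu])
    counts = np.triu(counts) + np.triu(counts, 1).T
    return ContactMap(exp.binning, counts, state="raw")


def calibration_null_spec(seed: int = 0) -> SyntheticSpec:
    """Structure-free null genome for checking z-score standardization.

    A homogeneous genome (60 chromosomes x 25 Mb at 1-Mb bins, no
    compartments/TADs/telomere boosts/biases) so every genomic distance
    pools exchangeable cells.  Sized so each analyzed distance has >= 1000
    cells (the +/-0.05 band on a mean of unit-variance z-scores needs that
    many for the check to outresolve its own sampling noise) and short-range
    cis cells carry >= ~50 counts, as in real megabase-binned maps, keeping
    count discreteness out of the quartile-based outlier filter.
    """
    sizes = {f"chr{i + 1}": 25_000_000 for i in range(60)}
    return SyntheticSpec(sizes, 1_000_000, trans_floor=0.08, depth=1.2e7, seed=seed)


def tad_scenario(
    n_chrom: int = 2,
    chrom_mb: int = 8,
    bin_size: int = 40_000,
    tad_spacing_bins: int = 25,
    tad_strength: float = 3.0,
    depth: float = 1e6,
    seed: int = 0,
) -> SyntheticSpec:
    """TAD-calling substrate: 40-kb maps with evenly planted domains.

    Defaults give 1-Mb domains (25 bins), matching the insulation square,
    at within/between contact ratio 3.
    """
    sizes = {f"chr{i + 1}": chrom_mb * 1_000_000 for i in range(n_chrom)}
    binning = make_binning(sizes, bin_size)
    return SyntheticSpec(
        sizes,
        bin_size,
        trans_floor=1e-3,
        tad_boundaries=even_tad_boundaries(binning, tad_spacing_bins),
        tad_strength=tad_strength,
        depth=depth,
        seed=seed,
    )


def compartment_scenario(
    n_chrom: int = 3,
    chrom_mb: int = 25,
    bin_size: int = 250_000,
    compartment_strength: float = 0.6,
    depth: float = 4e6,
    seed: int = 0,
    flip_bins=None,
) -> SyntheticSpec:
    """Plaid-compartment substrate at 250-kb resolution.

    ``flip_bins`` (global bin ordinals) get their eigenvector sign inverted,
    planting compartment switches for the two-condition analyses.
    """
    sizes = {f"chr{i + 1}": chrom_mb * 1_000_000 for i in range(n_chrom)}
    binning = make_binning(sizes, bin_size)
    rng = np.random.default_rng([seed, 77])
    e = block_compartment_profile(binning, block_bins=10, amplitude=0.8, rng=rng)
    if flip_bins is not None:
        e = e.copy()
        e[np.asarray(flip_bins)] *= -1
    return SyntheticSpec(
        sizes, bin_size,
        trans_floor=5e-3,
        compartment_profile=e,
        compartment_strength=compartment_strength,
        depth=depth,
        seed=seed,
    )


def genes_for_profile(binning: GenomeBinning, profile: np.ndarray, seed: int = 0,
                      genes_per_bin_rich: int = 8, genes_per_bin_poor: int = 2):
    """Synthetic gene intervals denser where the compartment profile is open.

    Emulates the gene-rich character of A compartments so the eigenvector
    orientation step has realistic evidence to work with.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 101])
    rows = []
    bins = binning.bins()
    for (chrom, start, end), e in zip(bins.itertuples(index=False), profile):
        n = genes_per_bin_rich if e > 0 else genes_per_bin_poor
        for pos in rng.integers(start, end - 1, size=n):
            rows.append({"chrom": chrom, "start": int(pos), "end": int(pos) + 1000})
    return GenomicIntervalSet(pd.DataFrame(rows))


def differential_scenario(
    n_chrom: int = 12,
    chrom_mb: int = 65,
    bin_size: int = 6_500_000,
    depth: float = 2e6,
    seed: int = 0,
    trans_block=None,
) -> SyntheticSpec:
    """Coarse-resolution substrate for the differential statistic.

    ``trans_block`` is a (chromA, chromB, (sa, ea, sb, eb), intensity)
    translocation-style planted trans contact block; None gives a null map.
    """
    sizes = {f"chr{i + 1}": chrom_mb * 1_000_000 for i in range(n_chrom)}
    return SyntheticSpec(
        sizes, bin_size,
        trans_floor=0.05,
        translocations=[trans_block] if trans_block else [],
        depth=depth,
        seed=seed,
    )


def telomere_scenario(
    n_chrom: int = 23,
    chrom_mb: int = 40,
    bin_size: int = 1_000_000,
    telomere_boost: float = 1.0,
    depth: float = 4e6,
    seed: int = 0,
) -> SyntheticSpec:
    """Genome of 23 chromosomes for end-to-end contact quantification."""
    sizes = {f"chr{i + 1}": chrom_mb * 1_000_000 for i in range(n_chrom)}
    return SyntheticSpec(
        sizes, bin_size,
        trans_floor=5e-3,
        telomere_boost=telomere_boost,
        end_fraction=0.05,
        depth=depth,
        seed=seed,
    )


def scaling_scenario(
    chrom_mb: int = 260,
    bin_size: int = 1_000_000,
    decay_exponent: float = 1.0,
    telomere_boost: float = 1.0,
    depth: float = 5e6,
    seed: int = 0,
) -> SyntheticSpec:
    """Single long chromosome for distance-scaling and end-upturn analyses."""
    return SyntheticSpec(
        {"chr1": chrom_mb * 1_000_000}, bin_size,
        decay_exponent=decay_exponent,
        telomere_boost=telomere_boost,
        end_fraction=0.05,
        depth=depth,
        seed=seed,
    )


def pairs_from_map(cmap: ContactMap, seed: int = 0):
    """Emit valid pairs (1-based positions) realizing a sampled count matrix.

    Each count in cell (i, j) becomes one pair with positions drawn
    uniformly within the two bins, so re-binning the pairs at the same
    resolution reproduces the matrix exactly.
    """
    rng = np.random.default_rng(seed)
    binning = cmap.binning
    bins = binning.bins()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    iu = np.triu_indices(binning.n_bins)
    counts = cmap.values[iu].astype(int)
    nz = counts > 0
    i_rep = np.repeat(iu[0][nz], counts[nz])
    j_rep = np.repeat(iu[1][nz], counts[nz])
    pos_a = rng.integers(starts[i_rep], ends[i_rep]) + 1
    pos_b = rng.integers(starts[j_rep], ends[j_rep]) + 1
    for k in range(len(i_rep)):
        yield chroms[i_rep[k]], int(pos_a[k]), chroms[j_rep[k]], int(pos_b[k])


def two_condition_scenario(
    n_large: int = 3,
    large_mb: int = 60,
    n_small: int = 4,
    small_mb: int = 20,
    bin_size: int = 1_000_000,
    depth: float = 2e6,
    seed: int = 0,
    compartment_strength: float = 0.6,
    tad_spacing_bins: int = 0,
    tad_strength: float = 1.0,
    small_chrom_factor_a: float = 2.0,
    telomere_boost_a: float = 3.0,
    switch_fraction: float = 0.12,
    with_bias: bool = True,
) -> tuple[SyntheticSpec, SyntheticSpec]:
    """Build condition-A ("tumor-like") and condition-B specs sharing a genome.

    Condition A differs from B by: raised trans contacts among the small
    chromosomes, telomere end clustering, and a fraction of compartment
    bins with flipped sign (split evenly between A->B and B->A switches,
    concentrated on the small chromosomes for the enrichment analyses).
    """
    sizes = {f"chr{i + 1}": large_mb * 1_000_000 for i in range(n_large)}
    sizes.update({f"chr{n_large + i + 1}": small_mb * 1_000_000 for i in range(n_small)})
    binning = make_binning(sizes, bin_size)
    rng = np.random.default_rng(seed)

    e_b = block_compartment_profile(binning, block_bins=8, amplitude=0.8, rng=rng)
    e_a = e_b.copy()
    small_chroms = [c for c in binning.chromosomes if sizes[c] == small_mb * 1_000_000]
    # plant switches preferentially on small chromosomes
    small_bins = np.concatenate([np.arange(binning.chrom_slice(c).start, binning.chrom_slice(c).stop) for c in small_chroms])
    n_switch = int(switch_fraction * binning.n_bins)
    flip = rng.choice(small_bins, size=min(n_switch, small_bins.size), replace=False)
    e_a[flip] = -e_a[flip]

    bias = rng.lognormal(0.0, 0.25, size=binning.n_bins) if with_bias else None
    tads = even_tad_boundaries(binning, tad_spacing_bins) if tad_spacing_bins else None

    common = dict(
        chrom_sizes=sizes,
        bin_size=bin_size,
        decay_exponent=1.0,
        trans_floor=2e-2,
        compartment_strength=compartment_strength,
        tad_boundaries=tads,
        tad_strength=tad_strength,
        depth=depth,
        bias=bias,
    )
    spec_a = SyntheticSpec(
        compartment_profile=e_a,
        small_chrom_trans_factor=(small_chroms, small_chrom_factor_a),
        telomere_boost=telomere_boost_a,
        seed=seed * 2 + 1,
        **common,
    )
    spec_b = SyntheticSpec(compartment_profile=e_b, seed=seed * 2 + 2, **common)
    return spec_a, spec_b
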