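# Methods

## Overview

`hicompare` implements a comparative Hi-C analysis chain: binned contact
matrices are balanced (ICE), distance-normalized into z-scores, and then
interrogated for condition differences at three structural scales —
individual interactions (replicate-null differential score), megabase
compartments (first-PC eigenvector and switch classification), and
sub-megabase domains (insulation-square TAD boundaries) — plus global
distance-decay scaling and telomeric end-to-end contact quantification.
Every stage is exercised against a synthetic generator with planted,
recoverable structure.

## Contact maps and balancing

A genome binning tiles an ordered chromosome set with fixed-width bins
(0-based, half-open; the terminal bin may be shorter and is kept as an
ordinary bin so telomeric signal is preserved). Contact maps are dense
symmetric matrices on that tiling with a per-bin exclusion mask; masked
bins enter every statistic as missing values, never as zeros.

ICE balancing is a symmetric Sinkhorn-type iteration: per-bin factors
`b_i` are updated by the square root of each bin's marginal relative to
the mean marginal until the coefficient of variation of unmasked marginals
falls below `tol` (default 1e-5, max 200 iterations; convergence state and
final CV are reported). Corrected values are `v_ij / (b_i b_j)`, rescaled
to preserve the total count; dividing by the total gives the relative form
in which overall depth and per-chromosome copy-number factors cancel
between samples. Zero-marginal bins are masked before balancing.

A caveat worth knowing: the equal-marginal target is not perfectly
compatible with a steep distance decay, because bins near chromosome ends
genuinely lack close neighbours. Balancing therefore assigns terminal bins
mildly elevated factors (a deterministic few-percent per-distance spread).
This is intrinsic to marginal balancing, not an implementation artifact,
and it shapes the design of the calibration study below.

## Distance-expected profile and z-scores

For each genomic separation `d`, unmasked cis values are pooled
(genome-wide by default; per-chromosome scope available), trimmed by a
1.5 x IQR fence (values outside `[Q1 - 1.5 IQR, Q3 + 1.5 IQR]` dropped),
and summarized by the mean and sample SD (ddof = 1). The two per-distance
curves are then smoothed across distance by lowess with span `alpha`
(default 0.01). Smoothing is done in log-log coordinates: a power-law
decay is locally linear there, so the local regression tracks the dominant
trend without the short-range bias that linear-coordinate smoothing
introduces on convex curves. `alpha = 0` disables smoothing (used by
oracle tests). A distance with fewer than two surviving values, or zero
SD, yields undefined z (never infinity).

Cis z-scores are `(v - mean(d)) / sd(d)`; the diagonal is undefined.
Trans cells are standardized against the pooled mean/SD of all unmasked
trans values. Pooling (rather than per-chromosome-pair standardization)
is deliberate: a pair-wide multiplicative difference — a translocation
block, or a trans-contact shift across a chromosome subset — would cancel
exactly under per-pair standardization, and those are precisely the
signals the differential analysis must see.

## Differential interaction score

Given z-maps for two conditions x two replicates, the per-cell statistic
is the mean of the four between-condition differences, standardized
against an empirical null of within-condition replicate differences
evaluated at `n_null` cells (default 500,000) sampled uniformly without
replacement (seeded) from cells defined in all four maps. Because
replicate order within a condition is arbitrary, the null is
sign-symmetric; we symmetrize it explicitly, so the null mean is exactly
zero and the scale is the RMS replicate difference. This also makes the
score exactly antisymmetric under a condition swap. Under a true null the
score is mildly under-dispersed (the four-way mean has variance ~1/2 of a
single replicate difference), which is conservative for flagging extremes.

The chromosome-set comparison collects trans scores for within-subset
pairs versus subset-vs-rest pairs and reports medians plus a two-sided
Wilcoxon rank-sum p value.

## Compartments

Per chromosome, the Pearson correlation matrix of cis z-score columns is
eigendecomposed; the first principal component's sign splits bins into two
mutually-interacting groups. The eigenvector is oriented so bins with
above-median gene density (interval-midpoint counts per bin from a
caller-supplied gene set) have positive mean value; positive = A (open,
gene-rich), negative = B. The per-chromosome correlation between the
oriented eigenvector and gene density is logged as orientation evidence;
chromosomes with fewer than 10 defined bins are left undefined. Sign
alone defines the label — no magnitude threshold.

Switches between two conditions are per-bin label pairs (A->A, B->B,
A->B, B->A; undefined if either side is). Enrichment of a switch
direction on a chromosome subset uses a 2x2 table (subset vs rest) x
(switched vs stable) with the Yates-corrected chi-square
`sum((|O - E| - 0.5)^2 / E)`, 1 df; a direction with zero switches
anywhere returns chi-square 0, p 1. Genes are assigned to the category of
the bin containing their midpoint (half-open convention; a midpoint on a
bin edge belongs to the right bin), and each switch direction is compared
with the pooled stable categories by rank-sum test.

## TAD boundaries and domains

The insulation score of bin `i` is the mean of unmasked cells in the
`w x w` square strictly upstream-by-downstream of the bin
(`rows i-w..i-1` x `cols i+1..i+w`; default `w = 25` bins = 1 Mb at
40 kb), undefined within `w` bins of chromosome ends or where more than
half the square is masked; the normalized track is log2 of raw over the
chromosome mean. Boundaries are local minima of the normalized track.
Strength is the mean depth below the highest flanking values within
500 kb on each side; boundaries weaker than 0.15 are discarded. Retained
cores are widened by 80 kb per side (200-kb final span, absorbing
replicate variation); overlapping widened intervals merge, keeping the
stronger core. The valley-depth strength formula is this package's
definition — the cutoff value 0.15 is standard but the formula behind it
is not uniquely determined, so absolute boundary counts from other
implementations are comparable only approximately.

Domains are the per-chromosome complement of widened boundary intervals,
minus caller-supplied exclusion intervals (centromere/telomere masks),
dropping fragments shorter than one bin. Boundary sets from two samples
are matched by widened-interval intersection; domain sets by reciprocal
overlap (>= 90% of both lengths, inclusive). Boundary-centred feature
profiles count feature midpoints in step-sized offset bins (defaults
+/-1 Mb by 25 kb) around boundary core midpoints, averaged over
boundaries.

## Scaling and telomeres

Scaling curves are means of unmasked cis values per log-spaced distance
bin (50 bins by default), genome-wide, per chromosome, or per arm (arms
from a centromere interval set); the log-log slope is fitted by least
squares over a caller-chosen distance range. The telomere statistic is
the mean contact between the first and last `end_fraction` (default 5%)
of each chromosome, intra-chromosomally, on relative (sum-normalized)
balanced values so depth and copy number do not confound cross-condition
comparison; conditions are compared per chromosome by rank-sum test.
Rank-sum tests throughout use the Mann-Whitney U formulation with the
exact small-sample distribution when there are no ties.

## Synthetic generator

The generator composes an expected intensity matrix from explicit
multiplicative parts — power-law cis decay `d^-alpha` (default exponent
1.0), plaid compartment factor `1 + c * e_i e_j`, within-domain factor
`tad_strength`, end-to-end factor `telomere_boost` on the terminal
`end_fraction` of each chromosome, flat trans floor with
translocation-block and chromosome-subset multipliers, per-bin biases and
per-chromosome copy-number factors — scales it to a target depth, and
draws independent Poisson counts per cell (symmetric; the diagonal
expectation is pinned to the distance-1 value since the diagonal is
excluded from analyses). Replicates are independent draws; all draws are
seeded and bit-reproducible.

What it emulates: distance decay, compartment plaid, domain blocks,
translocation-like trans blocks, condition-specific trans shifts,
telomere clustering, coverage bias, ploidy. What it does not:
restriction-fragment structure, read-level artifacts, distance-dependent
overdispersion, loops/stripes, and biological replicate variability
beyond counting noise. Passing recovery tests therefore demonstrates the
estimators' correctness and calibration under the stated noise model, not
robustness to every failure mode of real libraries.

### Study conditions

Scenario factories freeze the conditions each analysis runs under:

- `calibration_null_spec` — structure-free homogeneous genome (60
  chromosomes x 25 Mb, 1 Mb bins, trans floor 0.08, depth 1.2e7) for
  z-score calibration and bias recovery. It is sized so that (i) every
  analyzed distance pools >= 1000 cells — a +/-0.05 band on a mean of
  unit-variance scores is only meaningful with that many; (ii) short-range
  cis cells carry >= ~50 counts so count discreteness does not destabilize
  the IQR quartiles; and (iii) the trans-rich marginals dilute the
  end-bin balancing spread below Poisson noise. Calibration is evaluated
  at distances with >= 1000 pooled cells.
- `tad_scenario` — two 8-Mb chromosomes at 40 kb with 1-Mb planted
  domains, within/between ratio 3, depth 1e6.
- `compartment_scenario` — three 25-Mb chromosomes at 250 kb, plaid
  amplitude 0.6, depth 4e6; switches planted by flipping profile signs.
- `differential_scenario` — twelve 65-Mb chromosomes at 6.5 Mb with a
  substantial trans floor; optional 2x trans block.
- `telomere_scenario` — 23 x 40-Mb chromosomes at 1 Mb (5% ends = 2
  bins per side); `scaling_scenario` — one 260-Mb chromosome.

These problem sizes are scaled down from genome scale so that the entire
validation battery runs on a laptop in minutes while each check retains
the sample sizes its statistics require.

## Numerical and degenerate-input choices

- Sample SD (ddof = 1) everywhere an SD is estimated.
- SD = 0 or undefined profile -> missing z, never +/-inf.
- Insulation plateau minima resolve to the plateau center bin.
- Identical or constant samples short-circuit the rank-sum test to p = 1.
- The Yates continuity correction is clipped at zero so independence-like
  tables cannot produce a negative statistic.
- All random draws flow through `numpy.random.default_rng` seeded from
  explicit integer seed lists; identical inputs and seeds give identical
  outputs, including the differential null sample.

## Known limitations

- Genome-wide expected profiles mix per-chromosome cis levels (balancing
  leaves a per-chromosome scale freedom); on strongly heterogeneous
  karyotypes the per-chromosome profile scope is the better choice.
- The IQR outlier fence, applied to nearly-noiseless data, trims genuine
  tail mass and mildly inflates measured z dispersion; it exists for real
  data whose tails are artifactual.
- Boundary strength is implementation-defined (see above); compare counts
  across tools only qualitatively.
- The differential score is a screening statistic; no per-cell
  multiple-testing-corrected significance is attached.
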