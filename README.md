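# hicompare

Comparative Hi-C analysis in Python: from binned contact matrices through
ICE balancing and distance-normalized z-scores to condition differences at
three structural scales — individual chromatin interactions, A/B
compartments, and insulation-defined TADs — plus distance-decay scaling
and telomeric end-to-end contact quantification.

It is written for computational genomicists comparing chromosome
organization between two conditions (e.g. a tumor line against its normal
counterpart) from valid-pairs files or pre-binned matrices, with two
replicates per condition. A synthetic generator with planted structure
backs the full test battery, so every estimator ships with a known-truth
validation.

## The statistics at the core

**Balancing.** ICE (iterative correction): find per-bin factors `b_i`
such that `v_ij / (b_i b_j)` has equal marginals, absorbing coverage and
copy-number bias; the sum-normalized corrected map makes ploidy
differences cancel between samples.

**Distance z-scores.** For each genomic separation `d`, cis contacts are
summarized by an IQR-filtered mean and SD, lowess-smoothed over distance
(span 1%); each cell becomes `z = (v - mean(d)) / sd(d)`, removing the
dominant power-law decay.

**Differential interactions.** With condition/replicate z-maps A1, A2,
B1, B2, each cell's score is

    D = mean{A1-B1, A1-B2, A2-B1, A2-B2};   score = D / rms(null)

where the null is the set of replicate differences {A1-A2, B1-B2} at
500,000 randomly sampled interactions. Positive scores mark A-enriched
contacts; the score is exactly antisymmetric under a condition swap.

**Compartments.** Per chromosome, the first principal component of the
Pearson correlation of cis z-columns, sign-oriented by gene density:
positive = A (open), negative = B (closed). Bins switching label between
conditions (A->B, B->A) are tested for enrichment on chromosome subsets
with a Yates-corrected chi-square, and expression changes are aggregated
per switch category.

**TADs.** Insulation score: mean contact in a 1 Mb x 1 Mb square (25 x 25
bins at 40 kb) sliding along the diagonal; boundaries are valleys of the
log2-normalized track with strength >= 0.15, widened to 200 kb; domains
are the complement, matched across samples at 90% reciprocal overlap.

**Scaling & telomeres.** Mean contact per log-spaced distance bin
(genome / chromosome / arm scope) with log-log slope fits; mean contact
between the terminal 5% ends of each chromosome, compared across
conditions by Wilcoxon rank-sum test.

## Worked example

Simulate a two-condition study with planted TADs and analyze it:

```bash
hicompare simulate --out sim --seed 1 --bin-size 2000000 --depth 500000
hicompare bin --pairs sim/A1.pairs.tsv --chrom-sizes sim/chrom.sizes \
    --resolution 2000000 --out A1.dense.tsv
hicompare ice --matrix A1.dense.tsv --out A1.ice.tsv --mask-fraction 0
```

which prints, for example:

```
wrote 4 pairs files and truth tables to sim
binned 499842 pairs into 130 bins
converged=True iterations=16 marginal_cv=8.60e-06
```

`binned 499842 pairs` is the Poisson-sampled total around the requested
depth; `marginal_cv` is the post-balancing coefficient of variation of
bin marginals (machine-level balance at the default 1e-5 tolerance).

The numbered scripts under `analysis/` run the library end-to-end on
planted-truth data and narrate what they find; e.g.

```bash
python analysis/05_tad_boundaries.py
```

prints

```
boundary recovery over 10 seeds: precision min 1.000, recall min 1.000
replicate insulation correlation: 0.998
replicate boundary overlap: 14/14 (100%)
derived 16 domains between 14 boundaries
feature profile peaks at offset +12500 bp (written to results/)
```

— planted 1-Mb domains at contact ratio 3 are recovered exactly at ±1 bin
across seeds, and the insulation track reproduces between replicates.

The full pipeline on real inputs is `hicompare run-all --config cfg.json
--out results/run`, where the JSON config lists the four pairs files,
chromosome sizes, optional annotations (genes, centromeres, expression
table), resolutions and thresholds; it writes every stage's tables plus a
checksummed run manifest.

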