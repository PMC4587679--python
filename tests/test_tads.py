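"""Insulation squares, boundary calling, TAD derivation and classification."""

import numpy as np
import pandas as pd
import pytest

from hicompare.genome import ContactMap, GenomicIntervalSet, make_binning
from hicompare.normalize import ice_balance
from hicompare.simulate import sample_map, tad_scenario
from hicompare.tads import (
    BoundarySet,
    InsulationTrack,
    boundary_profile,
    call_boundaries,
    classify_boundaries,
    classify_tads,
    derive_tads,
    insulation,
)

BIN = 40_000


def make_track(values, bin_size=BIN):
    values = np.asarray(values, dtype=float)
    binning = make_binning({"c1": len(values) * bin_size}, bin_size)
    return InsulationTrack(binning, 2.0**values, values, w=5)


class TestInsulation:
    def test_uniform_matrix_gives_zero_normalized(self):
        n = 30
        binning = make_binning({"c1": n * BIN}, BIN)
        values = np.full((n, n), 4.0)
        cmap = ContactMap(binning, values, state="ice")
        track = insulation(cmap, w=5)
        defined = np.isfinite(track.normalized)
        assert defined.sum() == n - 10  # w bins undefined at each end
        assert np.allclose(track.normalized[defined], 0.0)

    def test_two_block_junction_is_the_minimum(self):
        """Within-block 10, between-block 1: insulation dips exactly at the
        junction, matching a direct mean over the square."""
        n = 40
        binning = make_binning({"c1": n * BIN}, BIN)
        values = np.ones((n, n))
        values[:20, :20] = 10.0
        values[20:, 20:] = 10.0
        cmap = ContactMap(binning, values, state="ice")
        w = 5
        track = insulation(cmap, w=w)
        defined = np.where(np.isfinite(track.normalized))[0]
        argmin = defined[np.argmin(track.normalized[defined])]
        # bins 19 and 20 straddle the junction and tie exactly (both squares
        # lie fully across the block border)
        assert argmin in (19, 20)
        direct20 = values[15:20, 21:26].mean()  # independent direct mean
        assert direct20 == 1.0
        assert track.raw[20] == pytest.approx(direct20)
        assert track.raw[19] == pytest.approx(values[14:19, 20:25].mean())
        assert track.raw[10] == pytest.approx(10.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        n, k = 50, 7
        base = rng.poisson(20, (n, n)).astype(float)
        base = (base + base.T) / 2
        shifted = np.full((n + k, n + k), base.mean())
        shifted[k:, k:] = base
        shifted = (shifted + shifted.T) / 2
        b1 = make_binning({"c1": n * BIN}, BIN)
        b2 = make_binning({"c1": (n + k) * BIN}, BIN)
        t1 = insulation(ContactMap(b1, base, state="ice"), w=5)
        t2 = insulation(ContactMap(b2, shifted, state="ice"), w=5)
        # raw insulation over the interior shifts by k
        inner = slice(10, n - 10)
        assert np.allclose(t1.raw[inner], t2.raw[10 + k:n - 10 + k])

    def test_short_chromosome_undefined(self):
        binning = make_binning({"c1": 8 * BIN}, BIN)
        cmap = ContactMap(binning, np.ones((8, 8)), state="ice")
        track = insulation(cmap, w=5)
        assert np.isnan(track.normalized).all()

    def test_normalization_mean_identity(self):
        """2^normalized averages to 1 per chromosome."""
        rng = np.random.default_rng(1)
        n = 40
        binning = make_binning({"c1": n * BIN}, BIN)
        v = rng.poisson(30, (n, n)).astype(float)
        v = (v + v.T) / 2
        track = insulation(ContactMap(binning, v, state="ice"), w=5)
        vals = track.normalized[np.isfinite(track.normalized)]
        assert np.mean(2.0**vals) == pytest.approx(1.0, rel=1e-9)


class TestCallBoundaries:
    def test_flat_track_has_no_boundaries(self):
        track = make_track(np.zeros(50))
        assert len(call_boundaries(track)) == 0

    def test_single_valley_strength_is_depth(self):
        vals = np.zeros(50)
        vals[25] = -1.0
        track = make_track(vals)
        bset = call_boundaries(track, strength_threshold=0.15)
        assert len(bset) == 1
        rec = bset.records.iloc[0]
        assert rec["strength"] == pytest.approx(1.0)
        assert rec["core_start"] == 25 * BIN
        # extended interval spans core +/- 80 kb = 200 kb total
        assert rec["end"] - rec["start"] == 200_000

    def test_weak_valley_rejected(self):
        vals = np.zeros(50)
        vals[25] = -0.10
        track = make_track(vals)
        assert len(call_boundaries(track, strength_threshold=0.15)) == 0

    def test_nearby_boundaries_merged_keeping_stronger(self):
        vals = np.zeros(50)
        vals[24] = -0.5
        vals[25] = -0.3
        track = make_track(vals)
        bset = call_boundaries(track)
        assert len(bset) == 1
        assert bset.records.iloc[0]["core_start"] == 24 * BIN


class TestDeriveTads:
    def test_one_boundary_two_tads(self):
        binning = make_binning({"c1": 50 * BIN}, BIN)
        records = pd.DataFrame([{"chrom": "c1", "core_start": 25 * BIN, "core_end": 26 * BIN,
                                 "start": 25 * BIN - 80_000, "end": 26 * BIN + 80_000,
                                 "strength": 1.0}])
        tads = derive_tads(BoundarySet(binning, records))
        assert len(tads) == 2
        assert tads.records.iloc[0]["start"] == 0

    def test_exclusion_removes_tad(self):
        binning = make_binning({"c1": 50 * BIN}, BIN)
        records = pd.DataFrame([{"chrom": "c1", "core_start": 25 * BIN, "core_end": 26 * BIN,
                                 "start": 25 * BIN - 80_000, "end": 26 * BIN + 80_000,
                                 "strength": 1.0}])
        excl = GenomicIntervalSet(pd.DataFrame([{"chrom": "c1", "start": 0, "end": 25 * BIN}]))
        tads = derive_tads(BoundarySet(binning, records), excl)
        assert len(tads) == 1
        assert tads.records.iloc[0]["start"] == 26 * BIN + 80_000


def bset_from_cores(binning, cores, chrom="c1", strength=1.0):
    rows = []
    for c in cores:
        rows.append({"chrom": chrom, "core_start": c * BIN, "core_end": (c + 1) * BIN,
                     "start": max(0, c * BIN - 80_000), "end": (c + 1) * BIN + 80_000,
                     "strength": strength})
    return BoundarySet(binning, pd.DataFrame(rows))


class TestClassifyBoundaries:
    def test_identical_sets_fully_overlap(self):
        binning = make_binning({"c1": 100 * BIN}, BIN)
        b = bset_from_cores(binning, [20, 50, 80])
        res = classify_boundaries(b, b)
        assert res["n_overlapping_1"] == 3
        assert res["n_set1_specific"] == 0

    def test_extra_boundary_is_specific(self):
        binning = make_binning({"c1": 100 * BIN}, BIN)
        b1 = bset_from_cores(binning, [20, 50, 80])
        b2 = bset_from_cores(binning, [20, 50])
        res = classify_boundaries(b1, b2)
        assert res["n_set1_specific"] == 1
        assert res["labels1"][2] == "set1-specific"

    def test_shifted_within_extension_still_overlaps(self):
        """Cores 4 bins (160 kb) apart: extended intervals intersect."""
        binning = make_binning({"c1": 100 * BIN}, BIN)
        b1 = bset_from_cores(binning, [50])
        b2 = bset_from_cores(binning, [54])
        res = classify_boundaries(b1, b2)
        assert res["n_overlapping_1"] == 1
        # 6 bins apart (240 kb): no intersection of 200-kb intervals
        b3 = bset_from_cores(binning, [56])
        assert classify_boundaries(b1, b3)["n_overlapping_1"] == 0

    def test_symmetry_of_overlap_counts(self):
        binning = make_binning({"c1": 100 * BIN}, BIN)
        b1 = bset_from_cores(binning, [10, 40, 70])
        b2 = bset_from_cores(binning, [12, 41, 90])
        r12 = classify_boundaries(b1, b2)
        r21 = classify_boundaries(b2, b1)
        assert r12["n_overlapping_1"] == r21["n_overlapping_2"]


class TestClassifyTads:
    def tad_set(self, binning, intervals):
        return __import__("hicompare.tads", fromlist=["TadSet"]).TadSet(
            binning, pd.DataFrame([{"chrom": "c1", "start": s, "end": e} for s, e in intervals])
        )

    def test_identical_sets_all_overlapping(self):
        binning = make_binning({"c1": 100 * BIN}, BIN)
        t = self.tad_set(binning, [(0, 1_000_000), (1_200_000, 2_000_000)])
        r1, r2 = classify_tads(t, t, 0.9)
        assert (r1.records["category"] == "overlapping").all()

    def test_half_overlap_is_specific_at_90(self):
        binning = make_binning({"c1": 100 * BIN}, BIN)
        t1 = self.tad_set(binning, [(0, 1_000_000)])
        t2 = self.tad_set(binning, [(500_000, 1_500_000)])
        r1, r2 = classify_tads(t1, t2, 0.9)
        assert r1.records.iloc[0]["category"] == "sample1-specific"
        assert r2.records.iloc[0]["category"] == "sample2-specific"

    def test_exact_90_percent_reciprocal_is_inclusive(self):
        binning = make_binning({"c1": 100 * BIN}, BIN)
        t1 = self.tad_set(binning, [(0, 1_000_000)])
        t2 = self.tad_set(binning, [(100_000, 1_100_000)])  # 900 kb shared, both 1 Mb
        r1, _ = classify_tads(t1, t2, 0.9)
        assert r1.records.iloc[0]["category"] == "overlapping"


class TestBoundaryProfile:
    def test_features_at_midpoints_spike_at_zero(self):
        binning = make_binning({"c1": 200 * BIN}, BIN)
        b = bset_from_cores(binning, [50, 100, 150])
        mids = [(c["core_start"] + c["core_end"]) // 2 for _, c in b.records.iterrows()]
        feats = GenomicIntervalSet(pd.DataFrame(
            [{"chrom": "c1", "start": m - 10, "end": m + 10} for m in mids]))
        prof = boundary_profile(b, feats, window=500_000, step=25_000)
        peak = prof.loc[prof["mean_frequency"].idxmax(), "offset_bp"]
        assert abs(peak) <= 12_500
        assert prof["mean_frequency"].max() == pytest.approx(1.0)
        assert (prof["mean_frequency"] > 0).sum() == 1

    def test_uniform_features_give_flat_profile(self):
        binning = make_binning({"c1": 2000 * BIN}, BIN)
        rng = np.random.default_rng(0)
        cores = rng.choice(np.arange(100, 1900), size=50, replace=False)
        b = bset_from_cores(binning, sorted(cores))
        starts = rng.integers(0, 2000 * BIN - 200, size=20_000)
        feats = GenomicIntervalSet(pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 100}))
        prof = boundary_profile(b, feats, window=1_000_000, step=25_000)
        m = prof["mean_frequency"]
        assert m.max() < 1.2 * m.mean()
        assert m.min() > 0.8 * m.mean()

    def test_empty_boundaries_empty_profile(self):
        binning = make_binning({"c1": 200 * BIN}, BIN)
        b = BoundarySet(binning, pd.DataFrame(columns=["chrom", "core_start", "core_end", "start", "end", "strength"]))
        feats = GenomicIntervalSet(pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]}))
        prof = boundary_profile(b, feats)
        assert (prof["mean_frequency"] == 0).all()


class TestGeneratorRecovery:
    def test_planted_boundaries_recovered(self):
        """Precision and recall vs planted positions at +/-1 bin."""
        spec = tad_scenario(seed=0)
        bal, _ = ice_balance(sample_map(spec, 1))
        bset = call_boundaries(insulation(bal))
        tp = fp = 0
        matched = set()
        for chrom, truth in spec.tad_boundaries.items():
            truth = set(truth)
            for b in bset.core_bins(chrom):
                hits = {t for t in truth if abs(t - b) <= 1}
                if hits:
                    tp += 1
                    matched.update((chrom, t) for t in hits)
                else:
                    fp += 1
        n_truth = sum(len(v) for v in spec.tad_boundaries.values())
        assert tp / (tp + fp) >= 0.9
        assert len(matched) / n_truth >= 0.9

    def test_replicate_insulation_correlates(self):
        spec = tad_scenario(seed=1)
        t1 = insulation(ice_balance(sample_map(spec, 1))[0])
        t2 = insulation(ice_balance(sample_map(spec, 2))[0])
        ok = np.isfinite(t1.normalized) & np.isfinite(t2.normalized)
        r = np.corrcoef(t1.normalized[ok], t2.normalized[ok])[0, 1]
        assert r >= 0.8

    def test_derived_tads_match_planted_blocks(self):
        spec = tad_scenario(seed=2)
        bal, _ = ice_balance(sample_map(spec, 1))
        tads = derive_tads(call_boundaries(insulation(bal)))
        # every planted block interior should lie inside exactly one TAD
        bin_size = spec.bin_size
        for chrom, bounds in spec.tad_boundaries.items():
            edges = [0] + list(bounds) + [spec.binning().chrom_nbins(chrom)]
            sub = tads.records[tads.records["chrom"] == chrom]
            for lo, hi in zip(edges[:-1], edges[1:]):
                mid = (lo + hi) // 2 * bin_size
                containing = sub[(sub["start"] <= mid) & (sub["end"] > mid)]
                assert len(containing) == 1
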