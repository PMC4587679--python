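"""ICE balancing and the distance z-score transform.

The ICE oracle is an intentionally naive alternating row/column scaling
iterated to convergence, independent of the production implementation.
"""

import numpy as np
import pytest
from dataclasses import replace

from hicompare.genome import ContactMap, make_binning
from hicompare.normalize import (
    distance_expected,
    ice_balance,
    zscore_transform,
)
from hicompare.simulate import SyntheticSpec, calibration_null_spec, sample_map


def naive_ice_oracle(values, n_iter=5000):
    """Brute-force alternating scaling: divide rows then columns by their
    marginal relative to the mean marginal, many times."""
    v = values.astype(float).copy()
    bias = np.ones(v.shape[0])
    for _ in range(n_iter):
        m = v.sum(axis=1)
        f = m / m.mean()
        v = v / np.sqrt(np.outer(f, f))
        bias *= np.sqrt(f)
    return v, bias


def make_map(values, bin_size=1_000_000):
    n = len(values)
    binning = make_binning({"c1": n * bin_size}, bin_size)
    return ContactMap(binning, np.asarray(values, dtype=float), state="raw")


class TestIceBalance:
    def test_equal_marginals_is_fixed_point(self):
        # circulant matrix: all marginals equal by construction
        row = np.array([0.0, 2, 1, 1, 2])
        values = np.array([np.roll(row, i) for i in range(5)])
        values = (values + values.T) / 2
        cmap = make_map(values)
        out, bias = ice_balance(cmap)
        b = bias.values
        assert np.allclose(b, b[0], rtol=1e-6)
        assert np.allclose(out.values, cmap.values, rtol=1e-6)

    def test_matches_naive_oracle_on_3x3(self):
        values = np.array([[0.0, 2, 4], [2, 0, 8], [4, 8, 0]])
        cmap = make_map(values)
        out, bias = ice_balance(cmap, tol=1e-8)
        marg = out.values.sum(axis=0)
        assert marg.std() / marg.mean() <= 1e-6

        oracle_v, oracle_b = naive_ice_oracle(values)
        oracle_v *= values.sum() / oracle_v.sum()
        assert np.allclose(out.values, oracle_v, rtol=1e-5)
        ratio = bias.values / oracle_b
        assert np.allclose(ratio, ratio[0], rtol=1e-5)  # equal up to scale

    def test_total_mass_preserved(self, random_map):
        out, _ = ice_balance(random_map)
        assert out.values.sum() == pytest.approx(random_map.values.sum())

    def test_idempotence(self, random_map):
        once, _ = ice_balance(random_map)
        again, bias2 = ice_balance(replace_state(once, "raw"))
        b = bias2.values
        assert np.nanmax(np.abs(b / np.nanmean(b) - 1)) < 1e-4

    def test_zero_marginal_bins_masked(self, small_binning):
        n = small_binning.n_bins
        values = np.ones((n, n))
        values[0, :] = 0
        values[:, 0] = 0
        out, _ = ice_balance(ContactMap(small_binning, values))
        assert out.mask[0]

    def test_copy_number_doubling_invariant_after_correction(self):
        """A chromosome at 2x ploidy ends with the same sum-normalized cis
        profile as the diploid baseline."""
        sizes = {"c1": 50_000_000, "c2": 40_000_000}
        kw = dict(bin_size=500_000, trans_floor=0.02, depth=2e7, seed=3)
        bal_cn, _ = ice_balance(sample_map(SyntheticSpec(sizes, copy_number={"c2": 2.0}, **kw), 0))
        bal_0, _ = ice_balance(sample_map(SyntheticSpec(sizes, **kw), 0))

        def cis_profile(bal):
            rel = bal.values / bal.total()
            s = bal.binning.chrom_slice("c2")
            blk = rel[s, s]
            return np.array([np.diagonal(blk, d).mean() for d in range(1, 30)])

        dev = np.max(np.abs(cis_profile(bal_cn) / cis_profile(bal_0) - 1))
        assert dev < 0.02

    def test_planted_bias_recovered(self):
        spec = calibration_null_spec(0)
        rng = np.random.default_rng(55)
        bias = rng.lognormal(0, 0.3, spec.binning().n_bins)
        m = sample_map(replace(spec, bias=bias), 0)
        _, bv = ice_balance(m)
        est = bv.values
        ok = np.isfinite(est)
        b_true = bias[ok] / np.exp(np.mean(np.log(bias[ok])))
        b_est = est[ok] / np.exp(np.mean(np.log(est[ok])))
        rms = np.sqrt(np.mean((b_est / b_true - 1) ** 2))
        assert rms < 0.05


def replace_state(cmap, state):
    out = cmap.copy()
    out.state = state
    return out


class TestDistanceExpected:
    def test_noiseless_distance_function_recovered(self):
        n = 30
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        values = 100.0 / np.maximum(d, 1)
        cmap = make_map(values)
        prof = distance_expected(cmap, alpha=0.0, iqr_factor=None)
        # the largest distance has a single observation: undefined by contract
        defined = prof.n_used >= 2
        assert np.allclose(prof.mean[defined], 100.0 / prof.distances[defined])
        assert np.allclose(prof.sd[defined], 0.0)
        assert np.isnan(prof.mean[~defined]).all()

    def test_single_distance_stats_without_smoothing(self):
        """Distance-1 values {1,2,3,4} give mean 2.5 and sample SD 1.291."""
        n = 5
        values = np.zeros((n, n))
        for i, v in enumerate([1.0, 2, 3, 4]):
            values[i, i + 1] = v
            values[i + 1, i] = v
        prof = distance_expected(make_map(values), alpha=0.0, iqr_factor=None)
        assert prof.mean[0] == pytest.approx(2.5)
        assert prof.sd[0] == pytest.approx(1.290994, abs=1e-5)

    def test_iqr_filter_drops_extreme_value(self):
        """1000 among {1,2,3} is outside the 1.5-IQR fence and excluded."""
        n = 5
        values = np.zeros((n, n))
        for i, v in enumerate([1.0, 2, 3, 1000]):
            values[i, i + 1] = v
            values[i + 1, i] = v
        prof = distance_expected(make_map(values), alpha=0.0, iqr_factor=1.5)
        assert prof.mean[0] == pytest.approx(2.0)
        assert prof.n_used[0] == 3


class TestZscoreTransform:
    def test_distance_only_matrix_gives_zero_z(self):
        n = 30
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        base = 100.0 / np.maximum(d, 1)
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1e-9, (n, n))
        values = base + (noise + noise.T)  # infinitesimal spread keeps SD > 0
        values = np.clip(values, 0, None)
        cmap = make_map(values)
        z = zscore_transform(cmap, distance_expected(cmap, alpha=0.0, iqr_factor=None))
        ok = np.isfinite(z.values)
        assert np.abs(z.values[ok]).max() < 10  # tiny noise, standardized

    def test_unit_offsets(self):
        """A value at mean(d) maps to z=0; at mean+SD to z=1."""
        n = 6
        values = np.zeros((n, n))
        for i, v in enumerate([1.0, 2, 3, 4, 5]):
            values[i, i + 1] = v
            values[i + 1, i] = v
        cmap = make_map(values)
        prof = distance_expected(cmap, alpha=0.0, iqr_factor=None)
        z = zscore_transform(cmap, prof)
        d1 = np.diagonal(z.values, 1)
        assert d1[2] == pytest.approx(0.0)  # value 3 == mean
        expect = (4 - 3) / prof.sd[0]
        assert d1[3] == pytest.approx(expect)

    def test_zero_sd_yields_missing_not_inf(self):
        n = 10
        values = np.full((n, n), 5.0)
        cmap = make_map(values)
        z = zscore_transform(cmap, distance_expected(cmap, alpha=0.0, iqr_factor=None))
        assert not np.isinf(z.values).any()
        assert np.isnan(np.diagonal(z.values, 1)).all()

    def test_trans_standardized_per_chromosome_pair(self):
        binning = make_binning({"c1": 3_000_000, "c2": 3_000_000}, 1_000_000)
        rng = np.random.default_rng(1)
        upper = rng.poisson(30.0, (6, 6)).astype(float)
        values = np.triu(upper) + np.triu(upper, 1).T
        cmap = ContactMap(binning, values, state="ice")
        z = zscore_transform(cmap, distance_expected(cmap, alpha=0.0))
        block = z.values[0:3, 3:6]
        assert block[np.isfinite(block)].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values[0, 4] == z.values[4, 0]  # symmetry preserved


def test_z_calibration_on_structure_free_map():
    """Per-distance z means stay near 0 and SDs near 1 on a null genome."""
    spec = calibration_null_spec(1)
    bal, _ = ice_balance(sample_map(spec, 0))
    z = zscore_transform(bal, distance_expected(bal))
    pools = {}
    for chrom in z.binning.chromosomes:
        s = z.binning.chrom_slice(chrom)
        blk = z.values[s, s]
        for d in range(1, blk.shape[0]):
            diag = np.diagonal(blk, d)
            pools.setdefault(d, []).append(diag[np.isfinite(diag)])
    checked = 0
    for d, lst in pools.items():
        vals = np.concatenate(lst)
        if vals.size >= 1000:
            checked += 1
            assert -0.05 <= vals.mean() <= 0.05
            assert 0.9 <= vals.std(ddof=1) <= 1.1
    assert checked >= 5
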