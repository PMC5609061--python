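"""Median normalization, two-copy rescaling, paired and pooled signals."""

import numpy as np
import pytest

from rdcnv.coverage import CoverageProfile
from rdcnv.normalize import (median_normalize, normalize_two_copy, paired_log2,
                             pool_controls)
from rdcnv.simulate import (SimTruth, default_gc_bias, simulate_rc,
                            synthetic_annotation)


def _profile(values, gc=None, mp=None, window_size=100):
    windows = synthetic_annotation(len(values), window_size, flat=True)
    if gc is not None:
        windows["gc"] = gc
    if mp is not None:
        windows["map"] = mp
    return CoverageProfile("s", windows, values)


class TestMedianNormalize:
    def test_single_bin_is_identity(self):
        p = _profile([10, 20, 30, 40, 50])
        out = median_normalize(p, "gc")
        assert out.values.tolist() == [10, 20, 30, 40, 50]

    def test_two_bin_hand_example(self):
        # bin A median 20, bin B median 10, overall median 15
        p = _profile([10, 20, 30, 10, 10, 20], gc=[10, 10, 10, 20, 20, 20])
        out = median_normalize(p, "gc")
        assert out.values.tolist() == [7.5, 15.0, 22.5, 15.0, 15.0, 30.0]

    def test_zero_median_bin_masked_to_zero(self):
        p = _profile([0, 10, 20, 30], gc=[5, 50, 50, 50])
        out = median_normalize(p, "gc")
        assert out.values[0] == 0.0  # masked downstream as non-positive

    def test_bin_medians_equalized(self):
        rng = np.random.default_rng(0)
        gc = rng.integers(30, 50, 2000)
        vals = rng.poisson(100, 2000) * (1 + 0.01 * (gc - 40))
        out = median_normalize(_profile(vals, gc=gc), "gc")
        m = np.median(out.values)
        for b in np.unique(gc):
            assert np.median(out.values[gc == b]) == pytest.approx(m, rel=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        gc = rng.integers(30, 50, 500)
        vals = rng.poisson(50, 500).astype(float)
        a = median_normalize(_profile(vals, gc=gc), "gc").values
        b = median_normalize(_profile(vals * 7.0, gc=gc), "gc").values
        assert np.allclose(b, a * 7.0)

    def test_sparse_bins_borrow_nearest_populated_median(self):
        rng = np.random.default_rng(2)
        gc = np.full(100, 40)
        gc[:2] = 80  # sparse bin, far from the populated one
        vals = rng.poisson(100, 100).astype(float)
        vals[:2] = 1000.0
        out = median_normalize(_profile(vals, gc=gc), "gc")
        # the outlier bin keeps the populated bin's median -> barely rescaled
        assert out.values[0] == pytest.approx(
            1000.0 * np.median(vals) / np.median(vals[2:]))


class TestNormalizeTwoCopy:
    def test_constant_profile_maps_to_two_copies(self):
        out = normalize_two_copy(_profile([50.0] * 20))
        assert np.allclose(out.norm, 2.0)
        assert np.allclose(out.log2, 0.0)

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(3)
        windows = synthetic_annotation(500, 100, seed=4)
        vals = rng.poisson(100, 500).astype(float)
        p = CoverageProfile("s", windows, vals)
        out = normalize_two_copy(p)
        # independent step-by-step recomputation of the three stages
        gc = windows["gc"].to_numpy()
        mp = np.round(windows["map"].to_numpy() * 10).astype(int)
        v = vals.copy()
        for bins in (gc, mp):
            m = np.median(v)
            counts = {b: int((bins == b).sum()) for b in np.unique(bins)}
            pop = [b for b, c in counts.items() if c >= 30]
            med = {b: np.median(v[bins == b]) for b in np.unique(bins)}
            new = v.copy()
            for b in np.unique(bins):
                src = b if (counts[b] >= 30 or not pop) else \
                    min(pop, key=lambda q: abs(q - b))
                new[bins == b] = v[bins == b] * m / med[src]
            v = new
        v = v * 2.0 / np.median(v)
        assert np.allclose(out.norm, v)
        assert np.allclose(out.log2[out.usable], np.log2(v[out.usable] / 2.0))

    def test_median_of_usable_windows_is_two(self):
        rng = np.random.default_rng(5)
        windows = synthetic_annotation(2000, 100, seed=6)
        p = CoverageProfile("s", windows, rng.poisson(80, 2000))
        out = normalize_two_copy(p)
        assert np.median(out.norm[out.usable]) == pytest.approx(2.0, rel=0.01)

    def test_gc_bias_removed(self):
        # injected GC bias: strong correlation before, none after
        from scipy.stats import pearsonr

        windows = synthetic_annotation(30_000, 10_000, seed=7)
        truth = SimTruth([], base_mean=2000.0, window_size=10_000, seed=8)
        p = simulate_rc(windows, truth, gc_bias=default_gc_bias)
        gc = windows["gc"].to_numpy()
        pre = pearsonr(p.values, gc).statistic
        out = normalize_two_copy(p)
        post = pearsonr(out.norm[out.usable], gc[out.usable]).statistic
        assert abs(pre) > 0.3
        assert abs(post) < 0.05

    def test_no_spurious_correction_on_unbiased_data(self):
        windows = synthetic_annotation(10_000, 100, seed=9)
        truth = SimTruth([], base_mean=500.0, window_size=100, seed=10)
        p = simulate_rc(windows, truth)  # flat biases
        out = normalize_two_copy(p)
        rescaled = p.values * 2.0 / np.median(p.values)
        rel = np.abs(out.norm[out.usable] - rescaled[out.usable]) \
            / rescaled[out.usable]
        assert np.median(rel) < 0.05


class TestPairedAndPooled:
    def test_identical_samples_give_zero_ratio(self):
        p = _profile([10.0, 20.0, 30.0, 40.0, 50.0])
        out = paired_log2(p, p)
        assert np.allclose(out.log2[out.usable], 0.0)

    def test_doubled_region_gives_log2_one(self):
        c = _profile([10.0] * 10)
        t = _profile([10.0] * 5 + [20.0] * 5)
        out = paired_log2(t, c)
        assert np.allclose(out.log2[5:], 1.0)
        assert np.allclose(out.log2[:5], 0.0)

    def test_zero_control_masked_not_infinite(self):
        c = _profile([10.0, 0.0, 10.0, 10.0, 10.0])
        t = _profile([10.0] * 5)
        out = paired_log2(t, c)
        assert not out.usable[1]
        assert np.all(np.isfinite(out.log2[out.usable]))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_log2(_profile([1.0] * 5), _profile([1.0] * 6))

    def test_pool_singleton_and_sum(self):
        a = _profile([1.0, 2.0, 3.0])
        b = _profile([3.0, 2.0, 1.0])
        assert pool_controls([a]).values.tolist() == [1, 2, 3]
        assert pool_controls([a, b]).values.tolist() == [4, 4, 4]

    def test_pool_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_controls([])
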