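"""Shifting-level-model segmentation: HMM construction, Viterbi, oracles."""

import numpy as np
import pytest

from conftest import enumerate_best_logprob
from rdcnv.slm import (SlmParams, baum_welch_refine, build_hmm, estimate_params,
                       path_logprob, viterbi_path, viterbi_segment)


class TestBuildHmm:
    def test_rows_sum_to_one_random_params(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lv = np.sort(rng.normal(0, 1, int(rng.integers(2, 8))))
            lv = lv + np.arange(lv.size) * 1e-6
            p = SlmParams(float(rng.normal()), float(rng.uniform(0.1, 2)),
                          float(rng.uniform(0.1, 2)), float(rng.uniform(0.01, 0.9)),
                          lv)
            _, logA, _, _ = build_hmm(p)
            assert np.allclose(np.exp(logA).sum(axis=1), 1.0)

    def test_symmetric_levels_give_equal_weights(self):
        p = SlmParams(0.0, 1.0, 0.1, 0.1, np.array([-0.7, 0.7]))
        logw, _, _, _ = build_hmm(p)
        assert np.allclose(np.exp(logw), [0.5, 0.5])

    def test_tiny_eta_decodes_constant_path(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        p = SlmParams(0.0, 1.0, 1.0, 1e-12, np.array([-1.0, 0.0, 1.0]))
        path = viterbi_path(x, p)
        assert np.unique(path).size == 1


class TestEstimateParams:
    def test_pure_noise_moments(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 10_000)
        p = estimate_params(x)
        assert abs(p.mu) < 0.05
        assert abs(p.sigma2_eps - 1.0) < 0.1

    def test_constant_signal_degenerates(self):
        p = estimate_params(np.zeros(100))
        assert p.degenerate
        segs = viterbi_segment(np.zeros(100))
        assert len(segs) == 1

    def test_short_signal_degenerates(self):
        assert estimate_params(np.arange(5, dtype=float)).degenerate


class TestViterbi:
    def test_constant_signal_one_segment(self):
        p = SlmParams(0.0, 1.0, 0.04, 0.1, np.array([-1.0, 0.0, 1.0]))
        segs = viterbi_segment(np.zeros(5), p)
        assert len(segs) == 1
        assert segs[0].level == 0.0

    def test_hand_instance_matches_enumeration(self):
        x = np.array([0.0, 0.1, -1.1, -0.9, -1.0])
        p = SlmParams(mu=-0.5, sigma2_mu=1.0, sigma2_eps=0.04, eta=0.1,
                      levels=np.array([-1.0, 0.0]))
        path = viterbi_path(x, p)
        assert p.levels[path].tolist() == [0.0, 0.0, -1.0, -1.0, -1.0]
        _, best = enumerate_best_logprob(x, p)
        assert path.tolist() == best.tolist()

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(2, 10))
            K = int(rng.integers(2, 4))
            lv = np.sort(rng.normal(0, 1, K)) + np.arange(K) * 1e-3
            p = SlmParams(float(rng.normal()), float(rng.uniform(0.1, 2)),
                          float(rng.uniform(0.05, 1)),
                          float(rng.uniform(0.01, 0.5)), lv)
            x = rng.normal(0, 1, n)
            lp_v = path_logprob(x, p, viterbi_path(x, p))
            lp_e, _ = enumerate_best_logprob(x, p)
            assert lp_v == pytest.approx(lp_e, abs=1e-9)

    def test_matches_hmmlearn_decoder(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.3, 80), rng.normal(1.5, 0.3, 40),
                            rng.normal(0, 0.3, 80)])
        p = estimate_params(x)
        logw, logA, lv, s2e = build_hmm(p)
        m = hmmlearn.GaussianHMM(n_components=lv.size,
                                 covariance_type="spherical", init_params="")
        m.startprob_ = np.exp(logw)
        m.transmat_ = np.exp(logA)
        m.means_ = lv[:, None]
        m.covars_ = np.full(lv.size, s2e)
        _, ref_path = m.decode(x[:, None], algorithm="viterbi")
        assert np.array_equal(ref_path, viterbi_path(x, p))

    def test_six_sigma_shift_breakpoint_recovery(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.normal(0, 1, 1000)
            x[500:] += 6.0
            segs = viterbi_segment(x)
            if any(abs(sg.start_w - 500) <= 1 for sg in segs[1:]):
                hits += 1
        assert hits >= 95

    def test_breakpoint_count_monotone_in_eta(self):
        etas = [1e-7, 1e-5, 1e-3, 1e-1]
        counts = np.zeros(len(etas))
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            x = rng.normal(0, 1, 300)
            for j, eta in enumerate(etas):
                counts[j] += len(viterbi_segment(x, eta=eta)) - 1
        assert all(counts[j] <= counts[j + 1] for j in range(len(etas) - 1))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.2, 60), rng.normal(1, 0.2, 60)])
        a = viterbi_segment(x)
        b = viterbi_segment(x + 3.0)
        assert [s.start_w for s in a] == [s.start_w for s in b]
        for sa, sb in zip(a, b):
            assert sb.level == pytest.approx(sa.level + 3.0, abs=1e-9)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.2, 50), rng.normal(1.2, 0.2, 30),
                            rng.normal(0, 0.2, 50)])
        fwd = viterbi_segment(x)
        rev = viterbi_segment(x[::-1])
        n = len(x)
        fwd_bounds = sorted(s.start_w for s in fwd[1:])
        rev_bounds = sorted(n - s.start_w for s in rev[1:])
        assert len(fwd_bounds) == len(rev_bounds)
        assert all(abs(a - b) <= 1 for a, b in zip(fwd_bounds, rev_bounds))

    def test_index_map_reexpands_masked_coordinates(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(2, 0.1, 40)])
        index_map = np.concatenate([np.arange(40), np.arange(50, 90)])
        segs = viterbi_segment(x, index_map=index_map)
        assert segs[0].start_w == 0
        assert segs[-1].end_w == 89
        assert segs[-1].start_w == 50


class TestBaumWelch:
    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.4, 60), rng.normal(1, 0.4, 40)])
        p0 = estimate_params(x)
        _, logliks = baum_welch_refine(x, p0, max_iter=6)
        assert len(logliks) >= 2
        assert all(b >= a - 1e-8 for a, b in zip(logliks, logliks[1:]))
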