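"""Shifting-level-model (SLM) segmentation of log2 coverage signals.

The SLM writes the observed signal as x_i = m_i + eps_i where eps_i is
white Gaussian noise with variance sigma2_eps and the unobserved mean
level m_i either persists (probability 1 - eta) or jumps to a fresh draw
from Normal(mu, sigma2_mu) (probability eta).  This is a hidden Markov
model once the continuous level is discretised onto a grid of K candidate
levels: the transition matrix is

    A[i, j] = (1 - eta) * 1[i == j] + eta * w[j]

with w[j] proportional to the Normal(mu, sigma2_mu) density at level j,
and emissions are Normal(x; level_j, sigma2_eps).  Viterbi decoding gives
the most probable piecewise-constant mean; maximal runs of one level are
the segments.

Parameters are estimated from the signal itself: the noise variance
sigma2_eps from the median absolute first difference (robust: a level
shift touches a single difference), and the level prior wide enough to
cover the candidate-level grid, so a jump to any plausible copy-number
level keeps non-negligible prior mass.  The default jump rate eta = 5e-3
expects a few breakpoints per thousand windows, the regime of CNV-bearing
genomic profiles; all of this is exposed in the API and the run
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.special import logsumexp
from scipy.stats import norm

DEFAULT_ETA = 5e-3
DEFAULT_OMEGA = 0.1
DEFAULT_KMAX = 40

#: E|d| of successive differences of N(0, s^2) noise is s*2/sqrt(pi); the
#: median of |d| is s*sqrt(2)*Phi^-1(3/4) = 0.9539 s.
_MAD_DIFF_SCALE = 0.9539


@dataclass
class SlmParams:
    """SLM / HMM parameters: level-process prior, noise, jump rate, grid."""

    mu: float
    sigma2_mu: float
    sigma2_eps: float
    eta: float
    levels: np.ndarray
    degenerate: bool = False  # constant / too-short signal: one segment

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        if not self.degenerate:
            if self.sigma2_mu <= 0 or self.sigma2_eps <= 0:
                raise ValueError("variances must be positive")
            if not 0 < self.eta < 1:
                raise ValueError("eta must lie in (0, 1)")
            if self.levels.size < 2 or np.any(np.diff(self.levels) <= 0):
                raise ValueError("levels must be strictly increasing, K >= 2")


@dataclass
class Segment:
    """A maximal run of constant decoded level, on window-index space."""

    chrom: str
    start_w: int  # first window index (inclusive)
    end_w: int  # last window index (inclusive)
    level: float  # decoded hidden level
    mean_obs: float  # empirical mean of member windows
    n_windows: int


def build_hmm(params: SlmParams):
    """Return (log_init, log_trans, levels, sigma2_eps) for the SLM HMM.

    The level weights w are the Normal(mu, sigma2_mu) densities at the
    candidate levels, normalised; they serve as both the initial state
    distribution and the landing distribution of a jump.
    """
    levels = params.levels
    logw = norm.logpdf(levels, loc=params.mu, scale=np.sqrt(params.sigma2_mu))
    logw = logw - logsumexp(logw)
    w = np.exp(logw)
    K = levels.size
    A = params.eta * np.tile(w, (K, 1))
    A[np.diag_indices(K)] += 1.0 - params.eta
    with np.errstate(divide="ignore"):
        logA = np.log(A)
    return logw, logA, levels, params.sigma2_eps


def estimate_params(signal, eta: float = DEFAULT_ETA, omega: float = DEFAULT_OMEGA,
                    k_max: int = DEFAULT_KMAX, levels=None,
                    baum_welch: bool = False, max_iter: int = 10) -> SlmParams:
    """Method-of-moments SLM parameters from the signal itself.

    mu is the signal mean.  The white-noise variance sigma2_eps comes
    from the median absolute successive difference (scaled for Gaussian
    noise), which is insensitive to the level shifts themselves; the
    level-process variance sigma2_mu is the larger of omega * var(signal)
    and (level span / 2)^2, so the jump prior keeps real mass on every
    candidate level.  Candidate levels are a uniform grid spanning the
    range of a 5-window running-median smoothing of the signal (robust to
    single-window outliers), with K = min(k_max, #distinct smoothed
    values).  Signals shorter than 10 windows or with (near-)zero
    variance fall back to a single-segment decode.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    mu = float(np.mean(x)) if n else 0.0
    s2 = float(np.var(x)) if n else 0.0
    if n < 10 or s2 < 1e-12:
        return SlmParams(mu, 1.0, 1.0, eta, np.array([mu, mu + 1.0]),
                         degenerate=True)
    if levels is None:
        smooth = median_filter(x, size=5, mode="nearest")
        k = int(min(k_max, np.unique(smooth).size))
        lo, hi = float(smooth.min()), float(smooth.max())
        if k < 2 or hi - lo < 1e-12:
            lo, hi = float(x.min()), float(x.max())
            k = max(k, 2)
        levels = np.linspace(lo, hi, k)
    levels = np.asarray(levels, dtype=float)
    sig_eps = float(np.median(np.abs(np.diff(x)))) / _MAD_DIFF_SCALE
    s2_eps = sig_eps ** 2 if sig_eps > 0 else (1.0 - omega) * s2
    span = float(levels[-1] - levels[0])
    s2_mu = max(omega * s2, (span / 2.0) ** 2, 1e-12)
    params = SlmParams(mu, s2_mu, max(s2_eps, 1e-12), eta, levels)
    if baum_welch:
        params = baum_welch_refine(x, params, max_iter=max_iter)[0]
    return params


def _emission_loglik(x, levels, sigma2_eps):
    return norm.logpdf(x[:, None], loc=levels[None, :],
                       scale=np.sqrt(sigma2_eps))


def viterbi_path(signal, params: SlmParams) -> np.ndarray:
    """Most probable hidden level sequence (indices into params.levels).

    Ties are broken toward staying in the previous state, which favours
    longer segments.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    logw, logA, levels, s2e = build_hmm(params)
    K = levels.size
    ll = _emission_loglik(x, levels, s2e)
    delta = logw + ll[0]
    psi = np.zeros((n, K), dtype=np.int64)
    idx = np.arange(K)
    for t in range(1, n):
        scores = delta[:, None] + logA  # [from, to]
        best_from = scores.argmax(axis=0)
        best = scores[best_from, idx]
        stay = scores[idx, idx] >= best  # tie -> stay
        best_from[stay] = idx[stay]
        best[stay] = scores[idx, idx][stay]
        delta = best + ll[t]
        psi[t] = best_from
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def path_logprob(signal, params: SlmParams, path) -> float:
    """Joint log-probability of a given level path under the HMM."""
    x = np.asarray(signal, dtype=float)
    logw, logA, levels, s2e = build_hmm(params)
    path = np.asarray(path, dtype=int)
    emit = (-0.5 * np.log(2 * np.pi * s2e)
            - (x - levels[path]) ** 2 / (2 * s2e)).sum()
    return float(logw[path[0]] + emit + logA[path[:-1], path[1:]].sum())


def _segments_from_path(path, levels, x, chrom, index_map=None):
    """Collapse a decoded path into maximal constant-level runs."""
    segs = []
    n = path.size
    start = 0
    for t in range(1, n + 1):
        if t == n or path[t] != path[t - 1]:
            first = start if index_map is None else int(index_map[start])
            last = (t - 1) if index_map is None else int(index_map[t - 1])
            segs.append(
                Segment(chrom, first, last, float(levels[path[start]]),
                        float(np.mean(x[start:t])), t - start)
            )
            start = t
    return segs


def viterbi_segment(signal, params: SlmParams | None = None, chrom: str = "chr",
                    index_map=None, **param_kw) -> list[Segment]:
    """Segment one chromosome's signal into constant-level runs.

    ``index_map`` optionally maps positions in ``signal`` (which excludes
    masked windows) back to global window indices so segments can span
    masked gaps with their original coordinates.
    """
    x = np.asarray(signal, dtype=float)
    if params is None:
        params = estimate_params(x, **param_kw)
    if params.degenerate or x.size < 2:
        if x.size == 0:
            return []
        first = 0 if index_map is None else int(index_map[0])
        last = x.size - 1 if index_map is None else int(index_map[-1])
        return [Segment(chrom, first, last, float(np.mean(x)),
                        float(np.mean(x)), x.size)]
    path = viterbi_path(x, params)
    return _segments_from_path(path, params.levels, x, chrom, index_map)


def breakpoints(segments: list[Segment]) -> list[int]:
    """Window indices where a new segment starts (excluding the first)."""
    return [s.start_w for s in segments[1:]]


def baum_welch_refine(signal, params: SlmParams, max_iter: int = 10,
                      tol: float = 1e-6):
    """EM refinement of (eta, sigma2_eps) with levels and mu held fixed.

    Treats the per-step jump indicator as an additional latent variable,
    so both updates are exact M-steps and the log-likelihood is monotone
    non-decreasing.  Returns (refined params, per-iteration log-liks).
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    logliks = []
    for _ in range(max_iter):
        logw, logA, levels, s2e = build_hmm(params)
        K = levels.size
        ll = _emission_loglik(x, levels, s2e)
        # forward-backward in log space
        alpha = np.zeros((n, K))
        beta = np.zeros((n, K))
        alpha[0] = logw + ll[0]
        for t in range(1, n):
            alpha[t] = ll[t] + logsumexp(alpha[t - 1][:, None] + logA, axis=0)
        for t in range(n - 2, -1, -1):
            beta[t] = logsumexp(logA + (ll[t + 1] + beta[t + 1])[None, :], axis=1)
        loglik = float(logsumexp(alpha[-1]))
        logliks.append(loglik)
        gamma = np.exp(alpha + beta - loglik)
        # expected jump mass: within A[i,j], fraction eta*w[j] came from a jump
        w = np.exp(logw)
        jump_frac = np.full((K, K), 1.0)
        diag = params.eta * w / ((1.0 - params.eta) + params.eta * w)
        jump_frac[np.diag_indices(K)] = diag
        jumps = 0.0
        for t in range(n - 1):
            xi = np.exp(alpha[t][:, None] + logA + (ll[t + 1] + beta[t + 1])[None, :]
                        - loglik)
            jumps += float((xi * jump_frac).sum())
        eta_new = min(max(jumps / max(n - 1, 1), 1e-12), 1 - 1e-12)
        s2e_new = float((gamma * (x[:, None] - levels[None, :]) ** 2).sum() / n)
        params = SlmParams(params.mu, params.sigma2_mu, max(s2e_new, 1e-12),
                           eta_new, levels)
        if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
            break
    return params, logliks
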