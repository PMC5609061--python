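"""Five-state copy-number classification of segments (FastCall-style).

Segment mean log2 values are modelled as a mixture of five truncated
Gaussians whose means are anchored at the cellularity-adjusted
copy-number expectations

    mu_k(c) = log2( max(c * CN_k + 2 * (1 - c), eps) / 2 ),   CN_k in 0..4

with eps = 0.1 copies keeping the double-loss mean finite (residual
mismapping gives nonzero coverage even in homozygous deletions).  The
cellularity c in (0, 1] is the fraction of cells carrying the alteration;
c < 1 shrinks every non-neutral mean toward 0.  EM (segments weighted by
their window counts) estimates the mixing weights, a shared standard
deviation and, when not supplied, c over a grid 0.1..1.0.

Each component is truncated to its bracket between consecutive cut
points; cuts sit at the copy-number midpoints, log2 of
(c*(CN_k + 0.5) + 2(1-c))/2, so on the raw two-copy scale the
neutral bracket at c = 1 is exactly (1.5, 2.5): a region whose median
coverage is 1.5 copies or less is never called neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

STATES = ["double_loss", "loss", "neutral", "gain", "multi_gain"]
STATE_CN = {"double_loss": 0, "loss": 1, "neutral": 2, "gain": 3, "multi_gain": 4}
EPS_COPIES = 0.1
CELLULARITY_GRID = np.round(np.arange(0.1, 1.01, 0.1), 2)
#: fixed log2 cut points used when too few segments support an EM fit
FALLBACK_BOUNDS = np.array([-1.5, -0.42, 0.32, 1.0])


def anchored_means(cellularity: float, eps: float = EPS_COPIES) -> np.ndarray:
    """Expected log2 ratios of the five states at cellularity c."""
    cn = np.arange(5, dtype=float)
    mix = cellularity * cn + 2.0 * (1.0 - cellularity)
    return np.log2(np.maximum(mix, eps) / 2.0)


def truncation_bounds(cellularity: float, eps: float = EPS_COPIES) -> np.ndarray:
    """Four ordered cut points between the five states (log2 scale)."""
    half = np.arange(4, dtype=float) + 0.5
    mix = cellularity * half + 2.0 * (1.0 - cellularity)
    return np.log2(np.maximum(mix, eps) / 2.0)


@dataclass
class CallModel:
    """Fitted five-state mixture: anchored means, shared sd, weights, cuts."""

    state_means: np.ndarray
    state_sd: float
    weights: np.ndarray
    cellularity: float
    truncation_bounds: np.ndarray
    converged: bool = True
    fallback: bool = False  # fixed thresholds, no EM fit

    def __post_init__(self):
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.diff(self.state_means) <= 0):
            raise ValueError("state means must be strictly increasing")

    def posteriors(self, x) -> np.ndarray:
        """Untruncated-mixture posterior over the five states, rows sum to 1."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        logp = (np.log(np.maximum(self.weights, 1e-300))[None, :]
                + norm.logpdf(x[:, None], self.state_means[None, :], self.state_sd))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def classify(self, x) -> np.ndarray:
        """State index per value from the truncation brackets.

        A value exactly on a cut point is assigned to the lower state, so
        a mean of log2(1.5/2) at c = 1 is still a loss.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.searchsorted(self.truncation_bounds, x, side="left")


def _segment_arrays(segments):
    """Accept a list of slm.Segment or a DataFrame with level/n_windows."""
    if isinstance(segments, pd.DataFrame):
        x = segments["mean_log2" if "mean_log2" in segments else "level"].to_numpy(float)
        w = segments["n_windows"].to_numpy(float)
    else:
        x = np.array([s.level for s in segments], dtype=float)
        w = np.array([s.n_windows for s in segments], dtype=float)
    return x, w


def fit_call_model(segments, cellularity: float | None = None,
                   max_iter: int = 200, tol: float = 1e-8) -> CallModel:
    """Fit the five-state mixture to segment means.

    With fewer than 5 segments the mixture is unidentifiable and a
    fixed-threshold model (c = 1 cut points) is returned instead.
    """
    x, w = _segment_arrays(segments)
    if x.size < 5:
        return CallModel(anchored_means(1.0), 0.2, np.full(5, 0.2), 1.0,
                         FALLBACK_BOUNDS.copy(), fallback=True)
    grid = [cellularity] if cellularity is not None else list(CELLULARITY_GRID)
    best = None
    for c in grid:
        mu = anchored_means(c)
        weights = np.full(5, 0.2)
        sd = max(float(np.sqrt(np.average((x - np.median(x)) ** 2, weights=w))), 0.05)
        loglik_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            logp = (np.log(np.maximum(weights, 1e-300))[None, :]
                    + norm.logpdf(x[:, None], mu[None, :], sd))
            lse = np.logaddexp.reduce(logp, axis=1)
            loglik = float(np.sum(w * lse))
            r = np.exp(logp - lse[:, None])
            wr = w[:, None] * r
            weights = wr.sum(axis=0) / w.sum()
            sd = float(np.sqrt((wr * (x[:, None] - mu[None, :]) ** 2).sum()
                               / w.sum()))
            sd = max(sd, 1e-3)
            if abs(loglik - loglik_prev) < tol * (1 + abs(loglik)):
                converged = True
                break
            loglik_prev = loglik
        model = CallModel(mu, sd, weights / weights.sum(), float(c),
                          truncation_bounds(float(c)), converged=converged)
        if best is None or loglik > best[0]:
            best = (loglik, model)
    return best[1]


def call_segments(segments, model: CallModel) -> pd.DataFrame:
    """Assign each segment a five-state call, posterior and copy number.

    Copy number follows the state (0, 1, 2, 3); multi_gain is refined to
    round(2 * 2^mean_log2), floored at 4, so amplifications of 5, 6, ...
    copies are genotyped from the signal itself.
    """
    if isinstance(segments, pd.DataFrame):
        df = segments.copy()
    else:
        df = pd.DataFrame(
            {
                "chrom": [s.chrom for s in segments],
                "start_w": [s.start_w for s in segments],
                "end_w": [s.end_w for s in segments],
                "n_windows": [s.n_windows for s in segments],
                "mean_log2": [s.level for s in segments],
                "mean_obs": [s.mean_obs for s in segments],
            }
        )
    x = df["mean_log2"].to_numpy(dtype=float)
    state_idx = model.classify(x)
    post = model.posteriors(x)
    cn = np.array([STATE_CN[STATES[k]] for k in state_idx])
    multi = state_idx == 4
    cn[multi] = np.maximum(4, np.round(2.0 * 2.0 ** x[multi]).astype(int))
    df["state"] = [STATES[k] for k in state_idx]
    df["cn"] = cn
    df["prob"] = post[np.arange(len(x)), state_idx]
    return df


def genotype_absolute(profile, calls: pd.DataFrame,
                      windows_index: dict | None = None) -> pd.DataFrame:
    """Absolute copy number per call from the two-copy-scaled signal.

    The estimate is round(median of norm values over the call's windows)
    (half away from zero).  ``cn_absolute`` may disagree with the state
    bracket (e.g. a noisy short segment); ``cn_consistent`` records the
    agreement, and the state-implied ``cn`` column is left untouched.
    Calls whose windows are all masked get a missing (-1) estimate.
    """
    out = calls.copy()
    norm_vals = profile.norm
    usable = profile.usable
    cn_abs = np.full(len(out), -1, dtype=int)
    consistent = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        lo, hi = int(row.start_w), int(row.end_w)
        sel = usable[lo:hi + 1]
        if not sel.any():
            continue
        med = float(np.median(norm_vals[lo:hi + 1][sel]))
        cn_abs[i] = int(np.sign(med) * np.floor(abs(med) + 0.5))
        st = row.state
        if st == "multi_gain":
            consistent[i] = cn_abs[i] >= 4
        else:
            consistent[i] = cn_abs[i] == STATE_CN[st]
    out["cn_absolute"] = cn_abs
    out["cn_consistent"] = consistent
    return out
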