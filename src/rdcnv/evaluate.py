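"""Evaluation statistics for read-depth CNV calling.

Implements the benchmarking toolkit used throughout the package:
distribution-fit distance (Kolmogorov-Smirnov D against moment-fitted
Poisson / negative binomial), the 50% reciprocal-overlap true-positive
rule, precision / recall / F-measure with size-class breakdowns,
breakpoint distances, and copy-number concordance (Pearson r, regression
slope, correct-classification rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

SIZE_CLASSES = {"small": (0, 20_000), "medium": (20_000, 100_000),
                "large": (100_000, np.inf)}
RO_THRESHOLD = 0.5

DEL_STATES = {"double_loss", "loss"}
DUP_STATES = {"gain", "multi_gain"}


class KsFit(NamedTuple):
    d: float
    family: str  # family actually fitted ("poisson" fallback when var <= mean)


def ks_fit_distance(values, family: str = "negative_binomial") -> KsFit:
    """KS distance between the empirical CDF and a moment-fitted model.

    Poisson is fitted by its mean; the negative binomial by mean and
    variance.  If the sample variance does not exceed the mean the NB is
    not defined by moments and the fit falls back to Poisson (flagged in
    the result).  D is the sup-norm difference evaluated on the integer
    support up to the sample maximum.
    """
    x = np.asarray(values)
    if x.size < 100:
        raise ValueError("need at least 100 values for a stable fit")
    mean = float(np.mean(x))
    var = float(np.var(x))
    if var < 1e-12:  # degenerate: compare against a point mass
        k = np.arange(0, int(np.max(x)) + 2)
        fitted = (k >= mean).astype(float)
        family_used = "degenerate"
    elif family == "poisson" or var <= mean:
        family_used = "poisson"
        k = np.arange(0, int(np.max(x)) + 2)
        fitted = stats.poisson.cdf(k, mean)
    elif family == "negative_binomial":
        family_used = "negative_binomial"
        p = mean / var
        r = mean ** 2 / (var - mean)
        k = np.arange(0, int(np.max(x)) + 2)
        fitted = stats.nbinom.cdf(k, r, p)
    else:
        raise ValueError(f"unknown family {family!r}")
    xs = np.sort(x)
    ecdf = np.searchsorted(xs, k, side="right") / x.size
    d = float(np.max(np.abs(ecdf - fitted)))
    return KsFit(d, family_used)


def reciprocal_overlap(a, b, threshold: float = RO_THRESHOLD):
    """Overlap fractions of two half-open intervals and the TP decision.

    Returns (overlap/len(a), overlap/len(b), both >= threshold).  The
    threshold is inclusive: exactly 50% reciprocal overlap is a match.
    """
    a0, a1 = a
    b0, b1 = b
    ov = max(0, min(a1, b1) - max(a0, b0))
    fa = ov / (a1 - a0)
    fb = ov / (b1 - b0)
    return fa, fb, bool(fa >= threshold and fb >= threshold)


def _direction(row) -> str:
    if "state" in row and isinstance(row["state"], str):
        if row["state"] in DEL_STATES:
            return "del"
        if row["state"] in DUP_STATES:
            return "dup"
        return "neutral"
    cn = int(row["cn"])
    return "del" if cn < 2 else ("dup" if cn > 2 else "neutral")


@dataclass
class OverlapMetrics:
    """TP/FP/FN counts and derived rates; precision is NA with no calls."""

    tp: int
    fp: int
    fn: int
    by_size: dict = field(default_factory=dict)

    @property
    def recall(self):
        n = self.tp + self.fn
        return self.tp / n if n else float("nan")

    tpr = recall

    @property
    def precision(self):
        n = self.tp + self.fp
        return self.tp / n if n else float("nan")

    @property
    def f_measure(self):
        p, r = self.precision, self.recall
        if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)

    def as_dict(self):
        d = {"tp": self.tp, "fp": self.fp, "fn": self.fn,
             "precision": self.precision, "recall": self.recall,
             "f_measure": self.f_measure}
        if self.by_size:
            d["by_size"] = {k: v.as_dict() for k, v in self.by_size.items()}
        return d


def _size_class(length):
    for name, (lo, hi) in SIZE_CLASSES.items():
        if lo < length <= hi or (lo == 0 and length <= hi):
            return name
    return "large"


def score_calls(calls: pd.DataFrame, truth: pd.DataFrame,
                require_state_match: bool = False,
                threshold: float = RO_THRESHOLD,
                by_size: bool = False) -> OverlapMetrics:
    """Match calls to truth events by reciprocal overlap.

    A truth event is detected (TP) when at least one call reciprocally
    overlaps it by >= threshold (and, with ``require_state_match``, the
    call direction agrees: loss-type vs cn<2, gain-type vs cn>2).  A call
    matching no event is an FP; extra calls overlapping an already
    matched event are neither TP nor FP.  precision = TP/(TP+FP),
    recall = TP/#truth.
    """
    calls = calls.reset_index(drop=True)
    truth = truth.reset_index(drop=True)
    call_matched = np.zeros(len(calls), dtype=bool)
    truth_matched = np.zeros(len(truth), dtype=bool)
    for ti, trow in truth.iterrows():
        tdir = _direction(trow) if require_state_match and "cn" in truth else None
        for ci, crow in calls.iterrows():
            if crow["chrom"] != trow["chrom"]:
                continue
            _, _, ok = reciprocal_overlap(
                (crow["start"], crow["end"]), (trow["start"], trow["end"]),
                threshold)
            if not ok:
                continue
            if tdir is not None and _direction(crow) != tdir:
                continue
            truth_matched[ti] = True
            call_matched[ci] = True
    tp = int(truth_matched.sum())
    fp = int((~call_matched).sum())
    fn = int((~truth_matched).sum())
    metrics = OverlapMetrics(tp, fp, fn)
    if by_size:
        for name in SIZE_CLASSES:
            tsel = truth[(truth["end"] - truth["start"]).map(_size_class) == name]
            csel = calls[(calls["end"] - calls["start"]).map(_size_class) == name]
            metrics.by_size[name] = score_calls(
                csel, tsel, require_state_match, threshold, by_size=False)
    return metrics


def breakpoint_distance(predicted_breakpoints, truth_events):
    """Per-boundary |predicted - true| distances in window units.

    ``predicted_breakpoints`` is a flat list of breakpoint positions;
    each truth event (start, end) contributes the distance from each of
    its two boundaries to the nearest predicted breakpoint, or NaN when
    there is no prediction at all.
    """
    bp = np.sort(np.asarray(list(predicted_breakpoints), dtype=float))
    out = []
    for s, e in truth_events:
        for bound in (s, e):
            if bp.size == 0:
                out.append(float("nan"))
            else:
                out.append(float(np.min(np.abs(bp - bound))))
    return out


def cn_concordance(predicted_cn, true_cn):
    """(Pearson r, regression slope, CCR) of predicted vs. true copies.

    CCR (correct classification rate) is the proportion of regions whose
    predicted integer copy number is exactly right.  Correlation and
    slope are NaN below 3 pairs or for constant inputs.
    """
    p = np.asarray(predicted_cn, dtype=float)
    t = np.asarray(true_cn, dtype=float)
    if p.size != t.size:
        raise ValueError("paired vectors required")
    ccr = float(np.mean(p == t)) if p.size else float("nan")
    if p.size < 3 or np.var(t) == 0 or np.var(p) == 0:
        return float("nan"), float("nan"), ccr
    r = float(stats.pearsonr(p, t).statistic)
    slope = float(stats.linregress(t, p).slope)
    return r, slope, ccr


def synthetic_detection_tpr(n_chroms: int, event_size: int, event_cns,
                            coverage_x: float, window_size: int,
                            seed: int, phi: float = 3.0,
                            require_state_match: bool = True):
    """TPR of the full pipeline on single-event synthetic chromosomes.

    Simulates ``n_chroms`` 1000-window chromosomes, each carrying one
    event of ``event_size`` windows with copy number cycling through
    ``event_cns``; runs normalize -> SLM -> FastCall on each and scores
    detection by >= 50% reciprocal overlap (direction-matched by
    default).  Returns (tpr, n_false_positive_calls, n_chroms).
    """
    from .pipeline import RunConfig, analyze_nocontrol
    from .simulate import make_synthetic_chromosome

    rng = np.random.default_rng(seed)
    cfg = RunConfig(window_size=window_size)
    event_cns = list(event_cns)
    tp = 0
    fp = 0
    for i in range(n_chroms):
        cn = event_cns[i % len(event_cns)]
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        profile, truth, windows = make_synthetic_chromosome(
            n_windows=1000, event_size=event_size, event_cn=cn,
            coverage_x=coverage_x, window_size=window_size, seed=sub_seed,
            phi=phi)
        result = analyze_nocontrol(profile, cfg)
        calls = result.calls[result.calls["state"] != "neutral"]
        truth_bed = truth.to_bed(windows)
        m = score_calls(calls, truth_bed, require_state_match=require_state_match)
        tp += m.tp
        fp += m.fp
    return tp / n_chroms, fp, n_chroms
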