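"""Median normalization of coverage for GC and mappability bias.

The correction is multiplicative: each window's value is rescaled by
``m / m_X`` where ``m_X`` is the median of all windows sharing the
window's covariate bin X (GC percent, or mappability bin) and ``m`` the
genome-wide median.  After correction the per-bin medians all equal the
overall median, which removes the smooth bias without modelling its
shape.  GC is corrected first, then mappability, each as a 1-D pass.

``normalize_two_copy`` then rescales so the genome-wide median sits at 2
(the diploid expectation) and log2-transforms, giving a signal where 0
means two copies, -1 a heterozygous deletion and +0.585 a single-copy
gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .grid import GC_SENTINEL

#: bins with fewer windows than this borrow the median of the nearest
#: populated bin (small-bin medians are too unstable to divide by).
MIN_BIN_COUNT = 30


@dataclass
class NormalizedProfile:
    """Bias-corrected coverage on the two-copy scale.

    ``norm`` is the corrected value rescaled so the genome-wide median of
    usable windows is 2; ``log2`` is ``log2(norm / 2)``; ``usable`` masks
    windows with unusable annotation or non-positive corrected value.
    """

    windows: pd.DataFrame
    norm: np.ndarray
    log2: np.ndarray
    usable: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = self.windows[["chrom", "start", "end"]].copy()
        df["norm"] = self.norm
        df["log2"] = self.log2
        df["usable"] = self.usable
        return df


def _bin_medians(values, bins, usable, min_bin_count=MIN_BIN_COUNT):
    """Per-bin medians with sparse bins borrowing the nearest populated bin.

    Returns (median_per_window, mask_of_valid_windows)."""
    uniq = np.unique(bins[usable])
    med = {}
    cnt = {}
    for b in uniq:
        sel = usable & (bins == b)
        med[b] = float(np.median(values[sel]))
        cnt[b] = int(sel.sum())
    populated = [b for b in uniq if cnt[b] >= min_bin_count]
    if populated:
        pop = np.asarray(populated, dtype=float)
        for b in uniq:
            if cnt[b] < min_bin_count:
                nearest = populated[int(np.argmin(np.abs(pop - float(b))))]
                med[b] = med[nearest]
    # else: every bin is sparse; each keeps its own median.
    out = np.full(len(values), np.nan)
    for b in uniq:
        out[bins == b] = med[b]
    return out


def median_normalize(profile: CoverageProfile, covariate: str = "gc",
                     min_bin_count: int = MIN_BIN_COUNT) -> CoverageProfile:
    """Correct each window value by ``m / m_X`` for one covariate.

    ``covariate`` is ``"gc"`` or ``"mappability"``.  Windows falling in a
    bin whose median is 0 are zeroed (they will be masked downstream as
    non-positive) rather than divided by zero.
    """
    windows = profile.windows
    values = np.asarray(profile.values, dtype=float)
    if covariate == "gc":
        bins = windows["gc"].to_numpy()
        usable = windows["usable"].to_numpy() & (bins != GC_SENTINEL)
    elif covariate == "mappability":
        bins = np.round(windows["map"].to_numpy() * 10).astype(int)
        usable = windows["usable"].to_numpy()
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    if not usable.any():
        raise ValueError("all windows are masked; nothing to normalize")
    m = float(np.median(values[usable]))
    m_x = _bin_medians(values, bins, usable, min_bin_count)
    out = values.copy()
    good = usable & np.isfinite(m_x) & (m_x > 0)
    out[good] = values[good] * m / m_x[good]
    out[usable & ~good] = 0.0  # zero-median bins: mask downstream
    return CoverageProfile(profile.sample_id, windows, out, mode=profile.mode,
                           mq_threshold=profile.mq_threshold)


def normalize_two_copy(profile: CoverageProfile,
                       min_bin_count: int = MIN_BIN_COUNT) -> NormalizedProfile:
    """GC then mappability median correction, two-copy rescale, log2.

    The genome-wide median of usable windows is mapped to 2 (most of a
    genome is diploid), so ``norm`` reads directly as copy number and
    ``log2 = log2(norm/2)`` is 0 at two copies.  Windows with unusable
    annotation or non-positive corrected value are masked.
    """
    corrected = median_normalize(profile, "gc", min_bin_count)
    corrected = median_normalize(corrected, "mappability", min_bin_count)
    windows = profile.windows
    gc = windows["gc"].to_numpy()
    usable = windows["usable"].to_numpy() & (gc != GC_SENTINEL)
    vals = corrected.values
    usable = usable & (vals > 0)
    if not usable.any():
        raise ValueError("all windows are masked after normalization")
    med = float(np.median(vals[usable]))
    norm = vals * (2.0 / med)
    log2 = np.full(len(norm), np.nan)
    log2[usable] = np.log2(norm[usable] / 2.0)
    return NormalizedProfile(windows, norm, log2, usable)


def paired_log2(test, control) -> NormalizedProfile:
    """log2 ratio of a test sample over its matched control.

    Both inputs are :class:`NormalizedProfile` (each sample corrected
    independently) or :class:`CoverageProfile` on the same grid.  Windows
    where the control signal is <= 0, or unusable in either sample, are
    masked rather than producing infinities.
    """
    tw, cw = test.windows, control.windows
    if len(tw) != len(cw) or not (
        (tw["start"].to_numpy() == cw["start"].to_numpy()).all()
        and (tw["chrom"].to_numpy() == cw["chrom"].to_numpy()).all()
    ):
        raise ValueError("test and control are on different window grids")

    def _vals(p):
        if isinstance(p, NormalizedProfile):
            return p.norm, p.usable
        return np.asarray(p.values, dtype=float), p.windows["usable"].to_numpy()

    tv, tu = _vals(test)
    cv, cu = _vals(control)
    usable = tu & cu & (cv > 0) & (tv > 0)
    log2 = np.full(len(tv), np.nan)
    log2[usable] = np.log2(tv[usable] / cv[usable])
    ratio = np.full(len(tv), np.nan)
    ratio[usable] = 2.0 * tv[usable] / cv[usable]
    return NormalizedProfile(tw, ratio, log2, usable)


def pool_controls(controls) -> CoverageProfile:
    """Window-wise sum of the control samples' raw values.

    The pooled profile is then used exactly like a single matched control
    (paired mode against the pool).
    """
    controls = list(controls)
    if not controls:
        raise ValueError("pool_controls requires at least one control")
    first = controls[0]
    total = np.zeros(len(first.windows), dtype=float)
    for c in controls:
        if len(c.windows) != len(first.windows) or not (
            c.windows["start"].to_numpy() == first.windows["start"].to_numpy()
        ).all():
            raise ValueError("control profiles are on different window grids")
        total += np.asarray(c.values, dtype=float)
    return CoverageProfile("pooled", first.windows, total, mode=first.mode,
                           mq_threshold=first.mq_threshold)


def write_normalized(profile: NormalizedProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
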