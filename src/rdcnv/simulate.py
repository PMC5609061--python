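"""Synthetic coverage data with known copy-number truth.

Window counts are drawn from a negative binomial with mean

    base_mean * (cn / 2) * gc_bias(gc) * map_bias(map)

and variance = phi * mean (phi > 1: overdispersed relative to Poisson, as
observed in real whole-genome read counts; default phi = 3, a moderate
index of dispersion).  base_mean is the expected two-copy count,
coverage_x * window_size / read_length for read counts.  Homozygous
deletions use a floor of 0.1 copies, emulating residual mismapped reads.

The default GC bias is a unimodal multiplicative factor peaking at 45%
GC and falling 40% at the extremes (coverage is empirically maximal in
the 35-60% GC band and drops at both ends); the default mappability bias
scales coverage down linearly in repetitive (low-mappability) windows.

The flagship protocol is the 1000-window synthetic chromosome carrying a
single deletion or duplication of N consecutive windows (N up to 500) at
a uniform random position, which exercises the entire downstream
pipeline with exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .grid import GC_SENTINEL, build_windows

DEFAULT_PHI = 3.0
DEFAULT_READ_LENGTH = 100
CN_FLOOR = 0.1  # copies assigned to CN 0 windows (residual mismapping)


def default_gc_bias(gc_bin):
    """Unimodal GC bias factor: 1.0 at 45% GC, 0.6 at the extremes."""
    g = np.asarray(gc_bin, dtype=float)
    f = 1.0 - 0.4 * ((g - 45.0) / 55.0) ** 2
    f = np.where(g == GC_SENTINEL, 1.0, f)
    return np.maximum(f, 0.2)


def default_map_bias(map_bin):
    """Linear mappability bias: unique windows 1.0, unmappable 0.4."""
    m = np.asarray(map_bin, dtype=float)
    return 0.4 + 0.6 * m


def flat_bias(_bin):
    """No bias (factor 1 everywhere)."""
    return np.ones_like(np.asarray(_bin, dtype=float))


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset.

    ``events`` are (chrom, start_window, end_window inclusive, cn) with
    cn != 2; everything outside events is two copies.
    """

    events: list
    base_mean: float
    dispersion: float = DEFAULT_PHI
    coverage_x: float | None = None
    window_size: int = 100
    seed: int | None = None

    def cn_per_window(self, windows: pd.DataFrame) -> np.ndarray:
        cn = np.full(len(windows), 2, dtype=int)
        chroms = windows["chrom"].to_numpy()
        for chrom, s, e, c in self.events:
            idx = np.flatnonzero(chroms == chrom)
            cn[idx[s:e + 1]] = c
        return cn

    def to_bed(self, windows: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for chrom, s, e, c in self.events:
            sub = windows[windows["chrom"] == chrom]
            rows.append((chrom, int(sub.iloc[s]["start"]), int(sub.iloc[e]["end"]), c))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])


def nb_counts(rng: np.random.Generator, mean, phi: float = DEFAULT_PHI):
    """Negative binomial draws with variance = phi * mean (phi=1: Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("negative means are not allowed")
    if phi <= 1.0:
        return rng.poisson(mean)
    n = mean / (phi - 1.0)
    p = 1.0 / phi
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n[pos], p)
    return out


def simulate_rc(windows: pd.DataFrame, truth: SimTruth,
                gc_bias=None, map_bias=None, phi: float | None = None,
                rng: np.random.Generator | None = None,
                sample_id: str = "sim") -> CoverageProfile:
    """Draw one NB count per window given the truth and bias functions.

    ``gc_bias`` / ``map_bias`` map a covariate bin to a positive
    multiplicative factor; ``None`` means flat (no bias).  Reproducible
    given ``truth.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    phi = truth.dispersion if phi is None else phi
    cn = truth.cn_per_window(windows).astype(float)
    cn = np.maximum(cn, CN_FLOOR)
    mean = truth.base_mean * cn / 2.0
    if gc_bias is not None:
        f = np.asarray(gc_bias(windows["gc"].to_numpy()), dtype=float)
        if np.any(f <= 0):
            raise ValueError("gc_bias factors must be positive")
        mean = mean * f
    if map_bias is not None:
        f = np.asarray(map_bias(windows["map"].to_numpy()), dtype=float)
        if np.any(f <= 0):
            raise ValueError("map_bias factors must be positive")
        mean = mean * f
    return CoverageProfile(sample_id, windows, nb_counts(rng, mean, phi), mode="rc")


def synthetic_annotation(n_windows: int, window_size: int = 100,
                         chrom: str = "chrS", seed: int | None = None,
                         gc_range=(20, 80), frac_unique: float = 0.7,
                         flat: bool = False) -> pd.DataFrame:
    """A window grid with synthetic GC / mappability annotations.

    GC bins are uniform over ``gc_range`` (small windows sample a wide GC
    spread); mappability is 1.0 for ``frac_unique`` of windows and
    uniform over 0.5..0.9 for the rest.  ``flat=True`` gives a single
    GC bin (45) and full mappability, for bias-free simulations.
    """
    windows = build_windows({chrom: n_windows * window_size}, window_size)
    if flat:
        windows["gc"] = 45
        windows["map"] = 1.0
        return windows
    rng = np.random.default_rng(seed)
    windows["gc"] = rng.integers(gc_range[0], gc_range[1] + 1, len(windows))
    mp = np.ones(len(windows))
    rep = rng.random(len(windows)) > frac_unique
    mp[rep] = rng.choice([0.5, 0.6, 0.7, 0.8, 0.9], rep.sum())
    windows["map"] = mp
    return windows


def make_synthetic_chromosome(n_windows: int = 1000, event_size: int = 50,
                              event_cn: int = 1, coverage_x: float = 30.0,
                              window_size: int = 100, seed: int | None = None,
                              phi: float = DEFAULT_PHI,
                              read_length: int = DEFAULT_READ_LENGTH,
                              chrom: str = "chrS"):
    """One synthetic chromosome with a single embedded CNV.

    1000 windows by default; one event of ``event_size`` consecutive
    windows at copy number ``event_cn`` (0..6, != 2) placed uniformly at
    random; everything else is two copies.  Counts are bias-free NB with
    two-copy mean coverage_x * window_size / read_length.

    Returns (CoverageProfile, SimTruth, windows).
    """
    if not 1 <= event_size <= n_windows // 2:
        raise ValueError(
            f"event_size must be in [1, {n_windows // 2}], got {event_size}"
        )
    if event_cn == 2 or not 0 <= event_cn:
        raise ValueError("event_cn must be a non-negative integer != 2")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n_windows - event_size + 1))
    windows = synthetic_annotation(n_windows, window_size, chrom=chrom, flat=True)
    base_mean = coverage_x * window_size / read_length
    truth = SimTruth([(chrom, start, start + event_size - 1, event_cn)],
                     base_mean, phi, coverage_x, window_size, seed)
    profile = simulate_rc(windows, truth, rng=rng)
    return profile, truth, windows


def simulate_region_medians(region_cns, n_windows_per_region: int = 50,
                            coverage_x: float = 30.0, window_size: int = 100,
                            n_background: int = 2000,
                            seed: int | None = None,
                            read_length: int = DEFAULT_READ_LENGTH,
                            phi: float = DEFAULT_PHI):
    """Per-region medians of the two-copy-scaled signal, with truth.

    Regions of ``n_windows_per_region`` windows at the given copy numbers
    are embedded in a two-copy background, the profile is normalized to
    two copies, and the median normalized value of each region is
    returned along with the true copy numbers.  The background is grown
    to at least twice the summed region length so the genome-wide median
    stays anchored at two copies, as in a real genome where altered
    regions are a small minority.  This is the substrate for
    median-threshold detection rules (deletion if median <= 1.5,
    duplication if >= 2.5) and for copy-number regression.
    """
    from .normalize import normalize_two_copy

    region_cns = list(region_cns)
    n_reg = len(region_cns)
    n_background = max(n_background, 2 * n_reg * n_windows_per_region)
    n_windows = n_background + n_reg * n_windows_per_region
    windows = synthetic_annotation(n_windows, window_size, flat=True)
    events = []
    pos = n_background
    for c in region_cns:
        if c != 2:
            events.append(("chrS", pos, pos + n_windows_per_region - 1, int(c)))
        pos += n_windows_per_region
    base_mean = coverage_x * window_size / read_length
    truth = SimTruth(events, base_mean, phi, coverage_x, window_size, seed)
    profile = simulate_rc(windows, truth, rng=np.random.default_rng(seed))
    norm = normalize_two_copy(profile)
    medians = np.empty(n_reg)
    pos = n_background
    for i in range(n_reg):
        sl = slice(pos, pos + n_windows_per_region)
        medians[i] = float(np.median(norm.norm[sl]))
        pos += n_windows_per_region
    return medians, np.asarray(region_cns, dtype=int)
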