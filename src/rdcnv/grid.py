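"""Genome window tiling and per-window GC / mappability annotation.

The read-depth approach tiles every chromosome into consecutive,
non-overlapping windows of fixed size and annotates each window with the
two covariates that dominate coverage bias in whole-genome sequencing:
local GC content (integer percent, 0..100) and mappability (binned to
multiples of 0.1, where 1.0 means every read starting in the window maps
uniquely).  Downstream normalization equalizes the per-bin coverage
medians, so the annotation defines the bias strata.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: gc value assigned to windows whose sequence is entirely ambiguous (N).
GC_SENTINEL = -1

WINDOW_COLUMNS = ["chrom", "start", "end", "gc", "map", "usable"]


def _round_half_away(x):
    """Round half away from zero (3.5 -> 4), element-wise."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_windows(chrom_lengths: Mapping[str, int], window_size: int) -> pd.DataFrame:
    """Tile each chromosome into consecutive non-overlapping windows.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.  Order is preserved.
    window_size
        Window length in bp (>= 50).  The last window of each chromosome
        may be shorter; it is flagged unusable when it covers less than
        half a window (a systematically low count would otherwise leak
        into normalization).

    Returns
    -------
    DataFrame with columns ``chrom start end gc map usable``; ``gc`` is
    initialised to :data:`GC_SENTINEL` and ``map`` to 0.0 until annotated.
    """
    if window_size < 50:
        raise ValueError(f"window_size must be >= 50, got {window_size}")
    if not chrom_lengths:
        raise ValueError("empty genome: no chromosomes given")
    frames = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gc": GC_SENTINEL,
                    "map": 0.0,
                    "usable": (ends - starts) * 2 >= window_size,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df[WINDOW_COLUMNS]


def _window_sequence(source, chrom: str, start: int, end: int) -> str:
    """Fetch a reference slice from a pyfaidx.Fasta-like object or a mapping."""
    if hasattr(source, "keys") and isinstance(source, dict):
        seq = source[chrom]
        if end > len(seq):
            raise ValueError(
                f"window {chrom}:{start}-{end} extends past reference ({len(seq)} bp)"
            )
        return str(seq[start:end])
    # pyfaidx.Fasta / pysam.FastaFile style
    record = source[chrom]
    if end > len(record):
        raise ValueError(
            f"window {chrom}:{start}-{end} extends past reference ({len(record)} bp)"
        )
    return str(record[start:end])


def annotate_gc(windows: pd.DataFrame, reference) -> pd.DataFrame:
    """Annotate each window with its integer GC percentage.

    GC% = round(100 * (#G + #C) / (#A + #C + #G + #T)); ambiguous bases are
    excluded from both numerator and denominator.  A window with no
    unambiguous base gets :data:`GC_SENTINEL` and is flagged unusable.
    Rounding is half away from zero.  The computation only counts G+C, so
    it is invariant under reverse-complement.

    ``reference`` may be a ``pyfaidx.Fasta``, a ``pysam.FastaFile`` or a
    plain ``dict`` of chromosome -> sequence string.
    """
    out = windows.copy()
    gc_vals = np.empty(len(out), dtype=np.int64)
    usable = out["usable"].to_numpy().copy()
    for i, row in enumerate(out.itertuples(index=False)):
        seq = _window_sequence(reference, row.chrom, int(row.start), int(row.end)).upper()
        g = seq.count("G") + seq.count("C")
        acgt = g + seq.count("A") + seq.count("T")
        if acgt == 0:
            gc_vals[i] = GC_SENTINEL
            usable[i] = False
        else:
            gc_vals[i] = int(_round_half_away(100.0 * g / acgt))
    out["gc"] = gc_vals
    out["usable"] = usable
    return out


def bin_mappability(values) -> np.ndarray:
    """Round mappability values to the nearest 0.1 bin (half rounds up).

    Idempotent: re-binning a binned value returns it unchanged.
    """
    v = np.asarray(values, dtype=float)
    return np.floor(v * 10.0 + 0.5) / 10.0


def annotate_mappability(windows: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Annotate windows with the mean mappability over their bases.

    ``track`` is a bedGraph-style frame with columns ``chrom start end value``
    (0-based half-open).  Positions absent from the track count as 0
    (unmappable), the conservative reading of an unreported position.  The
    per-window mean is rounded to the nearest 0.1 bin.
    """
    vals = track["value"].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("mappability track values must lie in [0, 1]")
    out = windows.copy()
    acc = np.zeros(len(out), dtype=float)
    # per-chromosome window lookup tables
    for chrom, wsub in out.groupby("chrom", sort=False):
        tsub = track[track["chrom"] == chrom]
        if tsub.empty:
            continue
        wstart = wsub["start"].to_numpy()
        wend = wsub["end"].to_numpy()
        widx = wsub.index.to_numpy()
        for t in tsub.itertuples(index=False):
            lo = np.searchsorted(wend, int(t.start), side="right")
            hi = np.searchsorted(wstart, int(t.end), side="left")
            for k in range(lo, hi):
                ov = min(int(t.end), wend[k]) - max(int(t.start), wstart[k])
                if ov > 0:
                    acc[widx[k]] += ov * float(t.value)
    lengths = (out["end"] - out["start"]).to_numpy(dtype=float)
    out["map"] = bin_mappability(acc / lengths)
    return out


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file into a ``chrom start end value`` frame."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].astype(str).str.startswith("track")]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df.reset_index(drop=True)
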