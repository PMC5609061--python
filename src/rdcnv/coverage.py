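"""Per-window raw coverage extraction from alignment files.

Two signals are supported:

* **RC** (read count): the number of filtered reads whose leftmost mapping
  position falls inside the window.  Appropriate when reads are shorter
  than the window (short-read data).
* **DOC** (depth of coverage): mean per-base aligned depth over the
  window.  Appropriate when reads are much longer than the window
  (single-molecule long-read data), where counting read starts would
  leave most windows empty even at high coverage.

Filters (both modes): primary, mapped, non-duplicate alignments with
mapping quality strictly greater than ``mq_threshold`` (default 10, i.e.
MQ <= 10 is discarded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import pysam


@dataclass
class CoverageProfile:
    """Per-window coverage values for one sample.

    ``values`` has one entry per row of ``windows``; integers for RC mode,
    non-negative reals for DOC mode.
    """

    sample_id: str
    windows: pd.DataFrame
    values: np.ndarray
    mode: str = "rc"  # "rc" | "doc"
    mq_threshold: int = 10

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.windows):
            raise ValueError(
                f"{len(self.values)} values for {len(self.windows)} windows"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("coverage values must be finite and >= 0")
        if self.mode not in ("rc", "doc"):
            raise ValueError(f"mode must be 'rc' or 'doc', got {self.mode!r}")

    def to_frame(self) -> pd.DataFrame:
        df = self.windows[["chrom", "start", "end"]].copy()
        df["value"] = self.values
        return df


def _passes_filters(read, mq_threshold: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and read.mapping_quality > mq_threshold
    )


def _open_alignment(source):
    if isinstance(source, pysam.AlignmentFile):
        return source, False
    af = pysam.AlignmentFile(str(source), "rb")
    return af, True


def _check_indexed(af: pysam.AlignmentFile):
    try:
        ok = af.check_index()
    except (ValueError, AttributeError):
        ok = False
    if not ok:
        raise ValueError(f"alignment file {af.filename!r} is not indexed")


def count_reads(alignment_source, windows: pd.DataFrame, mq_threshold: int = 10,
                sample_id: str = "sample") -> CoverageProfile:
    """Count filtered reads per window by leftmost mapping position (RC).

    Each passing read increments exactly the window containing its
    leftmost aligned reference coordinate (POS), regardless of strand.
    Chromosomes present in the alignment but absent from the window grid
    are skipped with a warning.
    """
    af, close = _open_alignment(alignment_source)
    try:
        _check_indexed(af)
        values = np.zeros(len(windows), dtype=np.int64)
        grid_chroms = set(windows["chrom"])
        missing = [c for c in af.references if c not in grid_chroms]
        if missing:
            warnings.warn(
                f"chromosomes {missing} present in alignments but absent from "
                "window grid; skipped"
            )
        for chrom, wsub in windows.groupby("chrom", sort=False):
            if chrom not in af.references:
                continue
            wstart = wsub["start"].to_numpy()
            wend = wsub["end"].to_numpy()
            widx = wsub.index.to_numpy()
            for read in af.fetch(chrom):
                if not _passes_filters(read, mq_threshold):
                    continue
                pos = read.reference_start
                k = np.searchsorted(wstart, pos, side="right") - 1
                if k >= 0 and pos < wend[k]:
                    values[widx[k]] += 1
    finally:
        if close:
            af.close()
    return CoverageProfile(sample_id, windows, values, mode="rc",
                           mq_threshold=mq_threshold)


def mean_depth(alignment_source, windows: pd.DataFrame, mq_threshold: int = 10,
               sample_id: str = "sample") -> CoverageProfile:
    """Mean per-base aligned depth per window (DOC).

    A read spanning several windows contributes to each in proportion to
    the aligned bases it places there; aligned blocks are the gapless
    M/=/X stretches, so deleted reference bases do not count as covered.
    """
    af, close = _open_alignment(alignment_source)
    try:
        _check_indexed(af)
        base_sums = np.zeros(len(windows), dtype=float)
        for chrom, wsub in windows.groupby("chrom", sort=False):
            if chrom not in af.references:
                continue
            wstart = wsub["start"].to_numpy()
            wend = wsub["end"].to_numpy()
            widx = wsub.index.to_numpy()
            tiled_end = wend[-1]
            for read in af.fetch(chrom):
                if not _passes_filters(read, mq_threshold):
                    continue
                for b0, b1 in read.get_blocks():
                    b1 = min(b1, tiled_end)
                    if b1 <= b0:
                        continue
                    lo = np.searchsorted(wend, b0, side="right")
                    hi = np.searchsorted(wstart, b1, side="left")
                    for k in range(lo, hi):
                        ov = min(b1, wend[k]) - max(b0, wstart[k])
                        if ov > 0:
                            base_sums[widx[k]] += ov
    finally:
        if close:
            af.close()
    lengths = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    return CoverageProfile(sample_id, windows, base_sums / lengths, mode="doc",
                           mq_threshold=mq_threshold)


def write_coverage(profile: CoverageProfile, path) -> None:
    """Write the per-window ``chrom start end value`` table (tab-delimited)."""
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_coverage(path, windows: pd.DataFrame | None = None,
                  mode: str = "rc", sample_id: str = "sample") -> CoverageProfile:
    """Round-trip a coverage table written by :func:`write_coverage`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if windows is None:
        windows = df[["chrom", "start", "end"]].copy()
        windows["gc"] = -1
        windows["map"] = 0.0
        windows["usable"] = True
    else:
        if len(df) != len(windows) or not (
            (df["start"].to_numpy() == windows["start"].to_numpy()).all()
            and (df["chrom"].to_numpy() == windows["chrom"].to_numpy()).all()
        ):
            raise ValueError("coverage table does not match the window grid")
    return CoverageProfile(sample_id, windows, df["value"].to_numpy(), mode=mode)
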