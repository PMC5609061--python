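"""Shared fixtures: tiny references, window grids and BAM builders.

All fixtures are generated programmatically; alignment fixtures are
written as BAM (sorted + indexed via pysam) into tmp_path at test time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from rdcnv.grid import build_windows


def enumerate_best_logprob(x, params):
    """Brute-force max joint log-probability over all K^n level paths.

    Independent oracle for the Viterbi decoder: scores every path
    explicitly (vectorised mixed-radix enumeration), no dynamic
    programming involved.
    """
    from rdcnv.slm import build_hmm

    x = np.asarray(x, dtype=float)
    logw, logA, levels, s2e = build_hmm(params)
    n, K = x.size, levels.size
    ids = np.arange(K ** n)
    paths = np.empty((ids.size, n), dtype=np.int8)
    for t in range(n):
        paths[:, t] = (ids // K ** (n - 1 - t)) % K
    emit = (-0.5 * np.log(2 * np.pi * s2e)
            - (x[None, :] - levels[paths]) ** 2 / (2 * s2e)).sum(axis=1)
    scores = logw[paths[:, 0]] + emit
    if n > 1:
        scores += logA[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), paths[best].astype(int)


@pytest.fixture
def two_window_grid():
    """Two 100 bp windows on one chromosome: [0,100), [100,200)."""
    return build_windows({"chr1": 200}, 100)


def make_bam(path, reads, chrom_lengths):
    """Write a sorted, indexed BAM from read dicts.

    Each read dict: chrom, pos, plus optional length (default 50), mq
    (default 60), flag_extra (e.g. duplicate/secondary), cigar.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_lengths)}
    unsorted = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment()
            length = r.get("length", 50)
            a.query_name = f"read{i}"
            a.query_sequence = "A" * length
            a.reference_id = tids[r["chrom"]]
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mq", 60)
            a.cigar = r.get("cigar", [(0, length)])
            a.flag = r.get("flag_extra", 0)
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            bam.write(a)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    return str(path)


@pytest.fixture
def bam_factory(tmp_path):
    def _make(reads, chrom_lengths, name="fixture.bam"):
        return make_bam(tmp_path / name, reads, chrom_lengths)

    return _make


@pytest.fixture
def flat_profile_factory():
    """Coverage profiles on flat-annotation synthetic grids."""
    from rdcnv.coverage import CoverageProfile
    from rdcnv.simulate import synthetic_annotation

    def _make(values, window_size=100, chrom="chrS"):
        values = np.asarray(values, dtype=float)
        windows = synthetic_annotation(len(values), window_size, chrom=chrom,
                                       flat=True)
        return CoverageProfile("s", windows, values)

    return _make
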