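"""End-to-end analysis in the three experimental designs.

* ``nocontrol`` — a single sample is median-normalized to two copies;
  best for population studies where most of the genome is diploid.
* ``paired`` — test and matched control are each bias-corrected, then
  the per-window log2 ratio is analysed; best for tumor/normal pairs.
* ``pooling`` — the control pool is summed window-wise and the test is
  compared to the pooled profile as in paired mode.

Each design feeds the same downstream chain: SLM segmentation of the
log2 signal (per chromosome, masked windows excised and coordinates
re-expanded) followed by five-state FastCall classification, and — in
nocontrol mode — absolute copy-number genotyping from the two-copy
scaled signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import fastcall, normalize, slm
from .coverage import CoverageProfile
from .normalize import NormalizedProfile

MODES = ("pooling", "paired", "nocontrol")


@dataclass
class RunConfig:
    """Tunable parameters of a run; flat and YAML-round-trippable."""

    mode: str = "nocontrol"
    window_size: int = 1000
    mq_threshold: int = 10
    coverage_mode: str = "rc"  # rc | doc
    eta: float = slm.DEFAULT_ETA
    omega: float = slm.DEFAULT_OMEGA
    k_max: int = slm.DEFAULT_KMAX
    baum_welch: bool = False
    cellularity: float | None = None  # None: estimated on a grid
    min_bin_count: int = normalize.MIN_BIN_COUNT
    seed: int | None = None
    n_processes: int = 1

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.window_size < 50:
            raise ValueError("window_size must be >= 50")

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class AnalysisResult:
    normalized: NormalizedProfile
    segments: list  # list of slm.Segment, global window indices
    calls: pd.DataFrame  # base-coordinate calls table
    model: fastcall.CallModel


def segment_normalized(profile: NormalizedProfile, cfg: RunConfig) -> list:
    """SLM-segment each chromosome of a normalized profile.

    Masked windows are removed before segmentation; the returned segments
    carry global window indices, so they may span masked gaps.
    """
    windows = profile.windows
    segments = []
    for chrom, wsub in windows.groupby("chrom", sort=False):
        idx = wsub.index.to_numpy()
        usable = profile.usable[idx]
        kept = idx[usable]
        if kept.size == 0:
            continue
        signal = profile.log2[kept]
        segs = slm.viterbi_segment(
            signal, chrom=chrom, index_map=kept,
            eta=cfg.eta, omega=cfg.omega, k_max=cfg.k_max,
            baum_welch=cfg.baum_welch)
        segments.extend(segs)
    return segments


def _calls_table(segments, model, windows: pd.DataFrame) -> pd.DataFrame:
    called = fastcall.call_segments(segments, model)
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    called["start"] = starts[called["start_w"].to_numpy()]
    called["end"] = ends[called["end_w"].to_numpy()]
    cols = ["chrom", "start", "end", "n_windows", "mean_log2", "state", "cn",
            "prob", "start_w", "end_w", "mean_obs"]
    return called[cols]


def _run_downstream(norm_profile: NormalizedProfile, cfg: RunConfig,
                    genotype: bool) -> AnalysisResult:
    segments = segment_normalized(norm_profile, cfg)
    model = fastcall.fit_call_model(segments, cellularity=cfg.cellularity)
    calls = _calls_table(segments, model, norm_profile.windows)
    if genotype:
        calls = fastcall.genotype_absolute(norm_profile, calls)
    return AnalysisResult(norm_profile, segments, calls, model)


def analyze_nocontrol(test: CoverageProfile, cfg: RunConfig) -> AnalysisResult:
    """Normalize a single sample to two copies, segment and call."""
    norm_profile = normalize.normalize_two_copy(test, cfg.min_bin_count)
    cfg = cfg if cfg.cellularity is not None else _with_cellularity(cfg, 1.0)
    return _run_downstream(norm_profile, cfg, genotype=True)


def analyze_paired(test: CoverageProfile, control: CoverageProfile,
                   cfg: RunConfig) -> AnalysisResult:
    """Bias-correct test and control independently, analyse their ratio."""
    t = normalize.normalize_two_copy(test, cfg.min_bin_count)
    c = normalize.normalize_two_copy(control, cfg.min_bin_count)
    ratio = normalize.paired_log2(t, c)
    return _run_downstream(ratio, cfg, genotype=False)


def analyze_pooling(test: CoverageProfile, controls, cfg: RunConfig) -> AnalysisResult:
    """Compare the test to the window-wise sum of the control pool."""
    pooled = normalize.pool_controls(controls)
    return analyze_paired(test, pooled, cfg)


def _with_cellularity(cfg: RunConfig, c: float) -> RunConfig:
    # nocontrol signals are on the absolute two-copy scale: c is 1 by
    # construction, so skip the grid search unless the user pinned a value.
    data = asdict(cfg)
    data["cellularity"] = c
    return RunConfig(**data)


def analyze(test: CoverageProfile, cfg: RunConfig, controls=None) -> AnalysisResult:
    """Dispatch on cfg.mode."""
    if cfg.mode == "nocontrol":
        return analyze_nocontrol(test, cfg)
    if controls is None or not list(controls):
        raise ValueError(f"mode {cfg.mode!r} requires control profiles")
    controls = list(controls)
    if cfg.mode == "paired":
        if len(controls) != 1:
            raise ValueError("paired mode takes exactly one control")
        return analyze_paired(test, controls[0], cfg)
    return analyze_pooling(test, controls, cfg)
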