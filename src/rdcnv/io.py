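"""Readers and writers for the tool's standard formats.

Tables are tab-delimited with headers; BED-like files are 0-based
half-open; VCF output is VCFv4.2 with symbolic <DEL>/<DUP> alleles
(1-based POS, INFO END/SVLEN/SVTYPE, FORMAT CN:CNS:CNP).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "start", "end", "n_windows", "mean_log2", "state",
                "cn", "prob"]


def write_windows(windows: pd.DataFrame, path) -> None:
    windows[["chrom", "start", "end", "gc", "map", "usable"]].to_csv(
        path, sep="\t", index=False)


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gc", "map"}
    if not required.issubset(df.columns):
        raise ValueError(f"window table missing columns {required - set(df.columns)}")
    if "usable" not in df.columns:
        df["usable"] = True
    return df


def write_segments(segments, path) -> None:
    rows = [(s.chrom, s.start_w, s.end_w, s.n_windows, s.level, s.mean_obs)
            for s in segments]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                "mean_log2", "mean_obs"]).to_csv(
        path, sep="\t", index=False)


def write_calls(calls: pd.DataFrame, path) -> None:
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    extra = [c for c in ("cn_absolute", "cn_consistent") if c in calls.columns]
    calls[cols + extra].to_csv(path, sep="\t", index=False)


def read_intervals(path) -> pd.DataFrame:
    """Read calls/truth intervals from a headered table or a plain BED."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom\t"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        cols = ["chrom", "start", "end"] + \
            [c for c in ("cn", "state") if c in df.columns]
        return df[cols]
    return read_bed(path)


def read_bed(path) -> pd.DataFrame:
    """BED-like table: chrom start end [cn].  Raises with the offending line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                row = {"chrom": parts[0], "start": int(parts[1]),
                       "end": int(parts[2])}
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: {line!r}") from exc
            if len(parts) > 3:
                try:
                    row["cn"] = int(parts[3])
                except ValueError:
                    row["name"] = parts[3]
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + [c for c in ("cn",) if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def write_metrics_json(metrics: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, default=_default)
        fh.write("\n")


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rdcnv
##ALT=<ID=DEL,Description="Deletion relative to the reference">
##ALT=<ID=DUP,Description="Duplication relative to the reference">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">
##FORMAT=<ID=CNS,Number=1,Type=String,Description="Copy number state">
##FORMAT=<ID=CNP,Number=1,Type=Float,Description="Posterior probability of the assigned state">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(calls: pd.DataFrame, path, sample: str = "SAMPLE") -> None:
    """Write non-neutral calls as VCFv4.2 symbolic-allele records.

    POS is 1-based; losses (CN < 2, including double loss) become <DEL>,
    gains <DUP>; SVLEN is negative for deletions.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(sample=sample))
        for i, row in enumerate(calls.itertuples(index=False), start=1):
            if row.state == "neutral":
                continue
            svtype = "DEL" if row.cn < 2 else "DUP"
            length = int(row.end) - int(row.start)
            svlen = -length if svtype == "DEL" else length
            info = f"END={int(row.end)};SVLEN={svlen};SVTYPE={svtype}"
            sample_field = f"{int(row.cn)}:{row.state}:{row.prob:.4f}"
            fh.write(
                f"{row.chrom}\t{int(row.start) + 1}\tcnv_{i}\tN\t<{svtype}>\t.\t"
                f"PASS\t{info}\tCN:CNS:CNP\t{sample_field}\n"
            )
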