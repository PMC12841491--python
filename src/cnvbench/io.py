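"""Readers and writers for the plain-text formats the pipeline exchanges.

Column conventions used by every module:

* bait frame:   ``chrom start end bait_id [gc] [mappability]`` (BED-derived,
  0-based half-open, sorted by (chrom, start))
* call frame:   ``chrom start end type sample caller``
* array frame:  ``chrom start end type sample snp_probes [manual_pass]``
  (read from 1-based inclusive coordinates, converted on load)
* depth matrix: TSV with ``bait_id`` index column and one column per sample,
  plus an optional sidecar of per-sample total mapped reads.

All writers emit sorted, tab-separated, newline-terminated files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import CnvType, normalize_chrom

log = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "start", "end", "type", "sample", "caller"]
ARRAY_COLUMNS = ["chrom", "start", "end", "type", "sample", "snp_probes"]


def _normalize_chrom_column(df: pd.DataFrame) -> pd.DataFrame:
    raw = df["chrom"].astype(str)
    norm = raw.map(normalize_chrom)
    if (raw != norm).any() and (raw == norm).any():
        log.info("mixed chromosome dialects unified by stripping 'chr' prefix")
    df = df.copy()
    df["chrom"] = norm
    return df


def sort_genomic(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)


def read_bed(path: str | Path, name_column: str | None = None) -> pd.DataFrame:
    """Read a 3+ column BED; optional 4th column is kept under ``name_column``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end"]
    if name_column is not None and df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = cols + [name_column]
    else:
        df = df.iloc[:, :3]
        df.columns = cols
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return sort_genomic(_normalize_chrom_column(df))


def write_bed(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    sort_genomic(df)[cols].to_csv(path, sep="\t", header=False, index=False)


def read_baits(path: str | Path) -> pd.DataFrame:
    """Bait BED with a mandatory 4th bait_id column; ids must be unique."""
    df = read_bed(path, name_column="bait_id")
    if "bait_id" not in df.columns:
        raise ValueError(f"{path}: bait BED needs a 4th (bait_id) column")
    if df["bait_id"].duplicated().any():
        dups = df.loc[df["bait_id"].duplicated(), "bait_id"].head().tolist()
        raise ValueError(f"{path}: duplicate bait ids, e.g. {dups}")
    return df


def write_baits(df: pd.DataFrame, path: str | Path) -> None:
    write_bed(df, path, extra=["bait_id"])


def read_calls(path: str | Path) -> pd.DataFrame:
    """Caller output table ``chrom start end type sample caller`` (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "caller": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing call columns {sorted(missing)}")
    df = df[CALL_COLUMNS].copy()
    df["type"] = df["type"].map(lambda t: CnvType.parse(t).value)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return sort_genomic(_normalize_chrom_column(df))


def write_calls(df: pd.DataFrame, path: str | Path) -> None:
    sort_genomic(df)[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_array_cnvs(path: str | Path) -> pd.DataFrame:
    """Array (CMA-style) CNV table; coordinates are 1-based inclusive on disk.

    Converted to 0-based half-open on read (start-1, end unchanged). An
    optional ``manual_pass`` boolean column is preserved when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(ARRAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing array columns {sorted(missing)}")
    keep = ARRAY_COLUMNS + (["manual_pass"] if "manual_pass" in df.columns else [])
    df = df[keep].copy()
    df["type"] = df["type"].map(lambda t: CnvType.parse(t).value)
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    df["snp_probes"] = df["snp_probes"].astype(np.int64)
    if (df["snp_probes"] < 0).any():
        raise ValueError(f"{path}: negative snp_probes")
    if "manual_pass" in df.columns:
        df["manual_pass"] = df["manual_pass"].astype(bool)
    return sort_genomic(_normalize_chrom_column(df))


def write_array_cnvs(df: pd.DataFrame, path: str | Path) -> None:
    """Write an array table back to 1-based inclusive coordinates."""
    out = sort_genomic(df).copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph: ``chrom start end score`` (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "score"], dtype={0: str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["score"] = df["score"].astype(float)
    return sort_genomic(_normalize_chrom_column(df))


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    sort_genomic(df)[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_depth_matrix(
    path: str | Path, totals_path: str | Path | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Bait x sample matrix of read counts or RPKM; optional totals sidecar.

    The sidecar is a two-column TSV ``sample total_mapped_reads``.
    """
    m = pd.read_csv(path, sep="\t", index_col="bait_id")
    if (m.values < 0).any():
        raise ValueError(f"{path}: negative depth values")
    totals = None
    if totals_path is not None:
        t = pd.read_csv(totals_path, sep="\t", dtype={"sample": str})
        totals = t.set_index("sample")["total_mapped_reads"].astype(np.int64)
        missing = set(m.columns) - set(totals.index)
        if missing:
            raise ValueError(f"{totals_path}: no totals for samples {sorted(missing)}")
        totals = totals.reindex(m.columns)
    return m, totals


def write_depth_matrix(
    m: pd.DataFrame, path: str | Path,
    totals: pd.Series | None = None, totals_path: str | Path | None = None,
) -> None:
    m.to_csv(path, sep="\t", index_label="bait_id")
    if totals is not None and totals_path is not None:
        totals.rename("total_mapped_reads").rename_axis("sample").reset_index().to_csv(
            totals_path, sep="\t", index=False
        )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
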