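"""Genomic interval data model and overlap/merge arithmetic.

All coordinates are 0-based, half-open (BED convention). Readers for
1-based inclusive sources convert at the boundary; nothing downstream
ever sees 1-based coordinates. Strand is ignored throughout: CNVs are
unstranded events.

Bulk collections (bait sets, call sets) are plain pandas DataFrames with
the column conventions of :mod:`cnvbench.io`; the dataclasses here are
the per-record views used by the scalar primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "CnvType",
    "GenomicInterval",
    "TargetBait",
    "CnvCall",
    "normalize_chrom",
    "overlaps",
    "overlap_length",
    "baits_hit",
    "baits_hit_many",
    "merge_intervals",
    "merge_frame",
]


class CnvType(str, Enum):
    """Copy-number event class: deletion or duplication."""

    DEL = "DEL"
    DUP = "DUP"

    @classmethod
    def parse(cls, token: str) -> "CnvType":
        t = str(token).strip().upper()
        if t in ("DEL", "DELETION", "LOSS"):
            return cls.DEL
        if t in ("DUP", "DUPLICATION", "GAIN"):
            return cls.DUP
        raise ValueError(f"unknown CNV type {token!r}; expected DEL or DUP")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mixed dialects compare equal."""
    c = str(chrom).strip()
    if not c:
        raise ValueError("empty chromosome name")
    return c[3:] if c.lower().startswith("chr") and len(c) > 3 else c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TargetBait:
    """One capture interval of the exome kit.

    ``gc`` and ``mappability`` are fractions in [0, 1]; ``None`` marks an
    explicitly missing annotation (e.g. no mappability coverage).
    """

    interval: GenomicInterval
    bait_id: str
    gc: float | None = None
    mappability: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("gc", self.gc), ("mappability", self.mappability)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CnvCall:
    """One caller event for one sample."""

    interval: GenomicInterval
    cnv_type: CnvType
    sample_id: str
    caller_id: str


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp under half-open semantics."""
    return (
        normalize_chrom(a.chrom) == normalize_chrom(b.chrom)
        and a.start < b.end
        and b.start < a.end
    )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases (0 when disjoint or on different chromosomes)."""
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _require_sorted_baits(baits: pd.DataFrame) -> None:
    key = baits[["chrom", "start"]]
    chrom_sorted = (key["chrom"].values[:-1] <= key["chrom"].values[1:])
    start_ok = (
        (key["chrom"].values[:-1] != key["chrom"].values[1:])
        | (key["start"].values[:-1] <= key["start"].values[1:])
    )
    if len(baits) > 1 and not (chrom_sorted & start_ok).all():
        raise ValueError(
            "bait set must be sorted by (chrom, start); sort it first"
        )


class _ChromIndex:
    """Per-chromosome arrays supporting overlap queries on a sorted bait set.

    Baits may overlap each other, so bait ends need not be monotone within a
    chromosome; queries use the running maximum of ends as an admissible
    lower bound, then filter exactly.
    """

    def __init__(self, baits: pd.DataFrame):
        _require_sorted_baits(baits)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms = baits["chrom"].map(normalize_chrom).values
        starts = baits["start"].to_numpy(np.int64)
        ends = baits["end"].to_numpy(np.int64)
        idx = np.arange(len(baits))
        for c in pd.unique(chroms):
            m = chroms == c
            s, e, i = starts[m], ends[m], idx[m]
            self.by_chrom[c] = (s, e, np.maximum.accumulate(e), i)

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row positions (in the original frame) of baits overlapping [start, end)."""
        entry = self.by_chrom.get(normalize_chrom(chrom))
        if entry is None:
            return np.empty(0, dtype=np.int64)
        s, e, cummax_e, i = entry
        hi = np.searchsorted(s, end, side="left")
        lo = np.searchsorted(cummax_e[:hi], start, side="right")
        cand = slice(lo, hi)
        keep = e[cand] > start
        return i[cand][keep]


def baits_hit(call: GenomicInterval, baits: pd.DataFrame) -> list[str]:
    """Bait ids with >= 1 bp overlap with ``call``, in genomic order.

    ``baits`` must be sorted by (chrom, start) and carry columns
    ``chrom start end bait_id``; an unsorted frame raises.
    """
    index = _ChromIndex(baits)
    rows = index.query(call.chrom, call.start, call.end)
    return baits["bait_id"].to_numpy()[rows].tolist()


def baits_hit_many(
    calls: pd.DataFrame, baits: pd.DataFrame
) -> pd.DataFrame:
    """Overlap-join call rows onto bait rows (>= 1 bp, half-open).

    Returns one row per (call, bait) overlap pair, with all columns of
    ``calls`` plus ``bait_id``. Calls hitting no bait contribute no rows.
    """
    index = _ChromIndex(baits)
    bait_ids = baits["bait_id"].to_numpy()
    call_rows: list[int] = []
    hit_ids: list[str] = []
    chroms = calls["chrom"].values
    starts = calls["start"].values
    ends = calls["end"].values
    for r in range(len(calls)):
        rows = index.query(chroms[r], int(starts[r]), int(ends[r]))
        call_rows.extend([r] * len(rows))
        hit_ids.extend(bait_ids[rows].tolist())
    out = calls.iloc[call_rows].reset_index(drop=True)
    out["bait_id"] = hit_ids
    return out


def merge_intervals(
    xs: list[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose half-open ranges overlap or lie within ``gap`` bp.

    Output is disjoint and sorted by (chrom, start). With gap=0,
    book-ended intervals ([0,10) + [10,20)) merge, so the covered base
    set is preserved exactly (union-of-covered-bases semantics).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if not xs:
        return []
    items = sorted(
        xs, key=lambda iv: (normalize_chrom(iv.chrom), iv.start, iv.end)
    )
    out: list[GenomicInterval] = []
    cur_chrom = normalize_chrom(items[0].chrom)
    cur_start, cur_end = items[0].start, items[0].end
    for iv in items[1:]:
        c = normalize_chrom(iv.chrom)
        if c == cur_chrom and iv.start <= cur_end + gap:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = c, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def merge_frame(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """merge_intervals over a ``chrom start end`` frame; returns a sorted frame."""
    merged = merge_intervals(
        [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ],
        gap=gap,
    )
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in merged],
            "start": [iv.start for iv in merged],
            "end": [iv.end for iv in merged],
        }
    )
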