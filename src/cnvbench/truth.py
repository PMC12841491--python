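"""Build the bait-level CNV truth set from array-style CNV tables.

Array (CMA) CNVs pass a fixed filter cascade — minimum SNP-probe support,
exclusion of highly polymorphic loci, and overlap with at least one capture
bait — and the survivors are expanded to per-(sample, bait) truth labels.
The bait (used interchangeably with "exon" throughout) is the atomic unit
of evaluation.

The polymorphic-locus rule is operationalised as: merge all input CNVs
across samples (gap=0); a merged locus is polymorphic when CNVs from more
than ``max_polymorphic_samples`` distinct samples overlap it; every CNV
overlapping such a locus is excluded. Filters are evaluated in the fixed
order manual-review -> probe-count -> polymorphic -> bait-overlap and the
audit records the first failing rule only, so audit files are
deterministic. Manual review itself is not automated: when the input
carries a boolean ``manual_pass`` column it is honoured, otherwise every
record passes that stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval, baits_hit_many, merge_frame

__all__ = ["TruthFilterConfig", "TruthExonSet", "filter_array_cnvs", "expand_to_truth_exons"]

REJECTION_RULES = ("manual_review", "probe_count", "polymorphic", "no_bait_overlap")


@dataclass(frozen=True)
class TruthFilterConfig:
    """Thresholds of the truth-set filter cascade.

    min_snp_probes: a CNV supported by fewer SNP probes than this is
        excluded (default 10).
    max_polymorphic_samples: a merged CNV locus carried by more distinct
        samples than this is polymorphic and all CNVs overlapping it are
        excluded (default 4).
    require_bait_overlap: drop CNVs that overlap no capture bait.
    """

    min_snp_probes: int = 10
    max_polymorphic_samples: int = 4
    require_bait_overlap: bool = True

    def __post_init__(self) -> None:
        if self.min_snp_probes < 1:
            raise ValueError("min_snp_probes must be >= 1")
        if self.max_polymorphic_samples < 0:
            raise ValueError("max_polymorphic_samples must be >= 0")


@dataclass
class TruthExonSet:
    """Per-(sample, bait) truth labels plus provenance counts.

    entries: frame ``sample bait_id truth_type`` with one row per unit;
        a bait hit by several same-sample CNVs of one type appears once.
    n_cnvs: surviving array CNV records behind the labels.
    n_samples: distinct samples contributing at least one label
        (the benchmark denominator cohort).
    """

    entries: pd.DataFrame
    n_cnvs: int
    n_samples: int

    @property
    def n_exons(self) -> int:
        return len(self.entries)

    def units(self) -> set[tuple[str, str, str]]:
        return set(
            zip(self.entries["sample"], self.entries["bait_id"], self.entries["truth_type"])
        )

    def write(self, baits: pd.DataFrame, path: str | Path) -> None:
        coords = baits.set_index("bait_id")[["chrom", "start", "end"]]
        grouped = (
            self.entries.groupby(["bait_id", "truth_type"])["sample"]
            .apply(lambda s: ",".join(sorted(s)))
            .reset_index()
        )
        out = grouped.join(coords, on="bait_id")
        out = out.sort_values(["chrom", "start", "bait_id"]).reset_index(drop=True)
        out[["bait_id", "chrom", "start", "end", "truth_type", "sample"]].rename(
            columns={"sample": "samples"}
        ).to_csv(path, sep="\t", index=False)


def _polymorphic_loci(cnvs: pd.DataFrame, max_samples: int) -> pd.DataFrame:
    """Merged loci (gap=0) overlapped by CNVs from > max_samples distinct samples."""
    if cnvs.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    loci = merge_frame(cnvs, gap=0)
    loci["bait_id"] = [f"locus{i}" for i in range(len(loci))]
    hits = baits_hit_many(cnvs, loci)
    per_locus = hits.groupby("bait_id")["sample"].nunique()
    poly = per_locus[per_locus > max_samples].index
    return loci[loci["bait_id"].isin(poly)][["chrom", "start", "end"]].reset_index(drop=True)


def _overlaps_any(cnvs: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Boolean per CNV row: overlaps >= 1 bp with any region."""
    flag = pd.Series(False, index=cnvs.index)
    if regions.empty or cnvs.empty:
        return flag
    regions = regions.copy()
    regions["bait_id"] = [f"r{i}" for i in range(len(regions))]
    probe = cnvs.reset_index().rename(columns={"index": "_row"})
    hits = baits_hit_many(probe, regions)
    flag.loc[hits["_row"].unique()] = True
    return flag


def filter_array_cnvs(
    cnvs: pd.DataFrame, cfg: TruthFilterConfig, baits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the truth-set filter cascade to an array CNV frame.

    Returns ``(kept, audit)``. The audit has one row per input CNV with a
    ``kept`` flag and the first failing ``reason`` (empty when kept),
    evaluated in the order manual_review -> probe_count -> polymorphic ->
    no_bait_overlap.
    """
    if cfg.require_bait_overlap and baits.empty:
        raise ValueError("bait overlap required but the bait set is empty")
    cnvs = cnvs.reset_index(drop=True)

    manual_fail = (
        ~cnvs["manual_pass"].astype(bool)
        if "manual_pass" in cnvs.columns
        else pd.Series(False, index=cnvs.index)
    )
    probe_fail = cnvs["snp_probes"] < cfg.min_snp_probes
    poly = _polymorphic_loci(cnvs, cfg.max_polymorphic_samples)
    poly_fail = _overlaps_any(cnvs, poly)
    if cfg.require_bait_overlap:
        bait_fail = ~_overlaps_any(cnvs, baits[["chrom", "start", "end"]])
    else:
        bait_fail = pd.Series(False, index=cnvs.index)

    reason = pd.Series("", index=cnvs.index, dtype=object)
    for name, fail in [
        ("manual_review", manual_fail),
        ("probe_count", probe_fail),
        ("polymorphic", poly_fail),
        ("no_bait_overlap", bait_fail),
    ]:
        reason[(reason == "") & fail] = name

    audit = cnvs.copy()
    audit["kept"] = reason == ""
    audit["reason"] = reason
    kept = cnvs[audit["kept"]].reset_index(drop=True)
    return kept, audit


def expand_to_truth_exons(kept: pd.DataFrame, baits: pd.DataFrame) -> TruthExonSet:
    """Expand surviving array CNVs to per-(sample, bait) truth labels.

    Every bait with >= 1 bp overlap with a kept CNV receives that CNV's
    type for that CNV's sample. A bait hit by several same-sample CNVs of
    one type counts once; a same-sample DEL/DUP conflict at one bait keeps
    both labels (labels are per (sample, bait, type), and the benchmark is
    always within-sample).
    """
    if kept.empty:
        entries = pd.DataFrame(columns=["sample", "bait_id", "truth_type"])
        return TruthExonSet(entries=entries, n_cnvs=0, n_samples=0)
    hits = baits_hit_many(kept, baits)
    entries = (
        hits[["sample", "bait_id", "type"]]
        .drop_duplicates()
        .rename(columns={"type": "truth_type"})
        .sort_values(["sample", "bait_id", "truth_type"])
        .reset_index(drop=True)
    )
    return TruthExonSet(
        entries=entries,
        n_cnvs=len(kept),
        n_samples=int(kept["sample"].nunique()),
    )
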