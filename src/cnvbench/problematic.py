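"""Caller-specific problematic regions and their genomic characterisation.

A bait is "problematic" for a caller when that caller emits a CNV call
overlapping it in more than a threshold fraction (default 10%) of the
whole cohort — recurrence this high across unrelated samples marks a
systematic calling artifact rather than real variation. Recurrence is
counted per bait over distinct samples, DEL and DUP pooled, against the
full cohort size (not only truth-positive samples); flagged baits are
merged (gap=0) into reportable regions.

Flagged baits are characterised against the rest of the kit by
mappability (mean per-base 35mer uniqueness), GC content, inter-sample
RPKM coefficient of variation and segmental-duplication overlap, using
repeated equal-size random draws from the non-problematic baits and a
two-sided Wilcoxon rank-sum test per feature and iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import baits_hit_many, merge_frame
from . import io as cio

__all__ = [
    "BaitRecurrence",
    "ProblematicMask",
    "BaitFeatures",
    "ComparisonResult",
    "recurrence",
    "build_mask",
    "rpkm",
    "rpkm_cv",
    "gc_content",
    "annotate",
    "compare_features",
]

FEATURES = ("mappability", "gc", "rpkm_cv")


@dataclass
class BaitRecurrence:
    """Per-bait distinct-sample calling recurrence for one caller."""

    caller_id: str
    cohort_size: int
    table: pd.DataFrame  # bait_id (index), n_samples_called, fraction


@dataclass
class ProblematicMask:
    """Baits flagged as problematic for one caller, plus merged regions."""

    caller_id: str
    threshold: float
    flagged_baits: set[str]
    merged_regions: pd.DataFrame  # chrom start end
    fractions: pd.Series  # recurrence fraction per flagged bait

    def write(self, out_bed: str | Path, out_tsv: str | Path) -> None:
        cio.write_bed(self.merged_regions, out_bed)
        (
            self.fractions.rename("fraction")
            .rename_axis("bait_id")
            .reset_index()
            .sort_values("bait_id")
            .to_csv(out_tsv, sep="\t", index=False)
        )


def recurrence(
    calls: pd.DataFrame,
    baits: pd.DataFrame,
    cohort_size: int,
    cnv_types: tuple[str, ...] | None = None,
) -> BaitRecurrence:
    """Count, per bait, distinct samples with >= 1 overlapping call.

    DEL and DUP are pooled by default; pass ``cnv_types=("DEL",)`` (or
    ``("DUP",)``) for a type-split analysis. ``cohort_size`` is the full
    cohort (all sequenced samples), the denominator of the recurrence
    fraction.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    if cnv_types is not None:
        calls = calls[calls["type"].isin(cnv_types)].reset_index(drop=True)
    callers = calls["caller"].unique() if len(calls) else ["none"]
    if len(callers) > 1:
        raise ValueError(f"recurrence expects one caller's calls, got {list(callers)}")
    n_seen = int(calls["sample"].nunique()) if len(calls) else 0
    if n_seen > cohort_size:
        raise ValueError(
            f"{n_seen} distinct samples observed but cohort_size={cohort_size}"
        )
    if len(calls):
        hits = baits_hit_many(calls, baits)
        counts = hits.groupby("bait_id")["sample"].nunique()
    else:
        counts = pd.Series(dtype=np.int64)
    table = pd.DataFrame(index=pd.Index(baits["bait_id"], name="bait_id"))
    table["n_samples_called"] = counts.reindex(table.index).fillna(0).astype(np.int64)
    table["fraction"] = table["n_samples_called"] / cohort_size
    return BaitRecurrence(caller_id=str(callers[0]), cohort_size=cohort_size, table=table)


def build_mask(
    rec: BaitRecurrence, baits: pd.DataFrame, threshold: float = 0.10
) -> ProblematicMask:
    """Flag baits with recurrence fraction STRICTLY above ``threshold``.

    "More than 10%" is strict: in a 180-sample cohort a bait called in 18
    samples (exactly 10%) is not flagged; 19 is.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    flagged = rec.table.index[rec.table["fraction"] > threshold]
    flagged_set = set(flagged)
    sub = baits[baits["bait_id"].isin(flagged_set)]
    merged = (
        merge_frame(sub, gap=0)
        if len(sub)
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    return ProblematicMask(
        caller_id=rec.caller_id,
        threshold=threshold,
        flagged_baits=flagged_set,
        merged_regions=merged,
        fractions=rec.table.loc[flagged, "fraction"].copy(),
    )


def region_recurrence_mask(
    calls: pd.DataFrame,
    baits: pd.DataFrame,
    cohort_size: int,
    threshold: float = 0.10,
) -> ProblematicMask:
    """Region-level alternative to per-bait recurrence.

    Atoms are the merged (gap=0) loci of all calls; a locus carried by
    strictly more than ``threshold`` of the cohort is flagged and every
    bait it overlaps joins the mask. Coarser than the per-bait default:
    one recurrent call neighbourhood can drag in adjacent quiet baits.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    callers = calls["caller"].unique() if len(calls) else ["none"]
    if len(callers) > 1:
        raise ValueError("expected one caller's calls")
    if calls.empty:
        return ProblematicMask(
            caller_id=str(callers[0]), threshold=threshold, flagged_baits=set(),
            merged_regions=pd.DataFrame(columns=["chrom", "start", "end"]),
            fractions=pd.Series(dtype=float),
        )
    loci = merge_frame(calls, gap=0)
    loci["bait_id"] = [f"locus{i}" for i in range(len(loci))]
    hits = baits_hit_many(calls, loci)
    per_locus = hits.groupby("bait_id")["sample"].nunique() / cohort_size
    flagged_loci = loci[loci["bait_id"].isin(per_locus[per_locus > threshold].index)]
    bait_hits = baits_hit_many(
        flagged_loci[["chrom", "start", "end"]], baits
    )
    flagged = set(bait_hits["bait_id"])
    sub = baits[baits["bait_id"].isin(flagged)]
    merged = (
        merge_frame(sub, gap=0)
        if len(sub)
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    fractions = pd.Series(np.nan, index=pd.Index(sorted(flagged), name="bait_id"))
    return ProblematicMask(
        caller_id=str(callers[0]), threshold=threshold,
        flagged_baits=flagged, merged_regions=merged, fractions=fractions,
    )


def union_mask(masks: list[ProblematicMask], baits: pd.DataFrame) -> ProblematicMask:
    """Union of several callers' masks, for consensus workflows."""
    if not masks:
        raise ValueError("need at least one mask")
    flagged = set().union(*(m.flagged_baits for m in masks))
    sub = baits[baits["bait_id"].isin(flagged)]
    merged = (
        merge_frame(sub, gap=0)
        if len(sub)
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    fractions = pd.concat([m.fractions for m in masks]).groupby(level=0).max()
    return ProblematicMask(
        caller_id="+".join(m.caller_id for m in masks),
        threshold=min(m.threshold for m in masks),
        flagged_baits=flagged, merged_regions=merged,
        fractions=fractions.reindex(sorted(flagged)),
    )


def rpkm(counts: pd.DataFrame, totals: pd.Series, baits: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase of target per million mapped reads.

    rpkm = reads * 1e9 / (bait_length_bp * total_mapped_reads), per bait
    (row) and sample (column).
    """
    lengths = (baits["end"] - baits["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("bait lengths must be > 0")
    lengths = pd.Series(lengths, index=baits["bait_id"]).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"depth matrix rows not in the bait set, e.g. {missing}")
    totals = totals.reindex(counts.columns)
    bad = totals.index[(totals.isna()) | (totals <= 0)].tolist()
    if bad:
        raise ValueError(f"zero/missing total mapped reads for samples {bad}")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def rpkm_cv(m: pd.DataFrame) -> pd.Series:
    """Inter-sample coefficient of variation per bait: sd(n-1) / mean.

    NaN (missing, not 0) where the mean is 0; such baits are excluded from
    downstream comparisons.
    """
    if m.shape[1] < 2:
        raise ValueError("rpkm_cv needs at least 2 samples")
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean == 0] = np.nan
    return cv


def gc_content(chrom: str, start: int, end: int, fasta) -> float:
    """G+C fraction of the non-N bases of [start, end); NaN when all-N.

    ``fasta`` is a pyfaidx.Fasta (or any mapping of name -> sliceable
    sequence). Intervals outside the sequence bounds raise.
    """
    names = {str(k): str(k) for k in fasta.keys()}
    # tolerate chr-prefix dialect differences between baits and FASTA
    lookup = {n.removeprefix("chr"): n for n in names}
    key = names.get(chrom) or lookup.get(str(chrom).removeprefix("chr"))
    if key is None:
        raise KeyError(f"chromosome {chrom!r} not in sequence source")
    seq_len = len(fasta[key])
    if start < 0 or end > seq_len:
        raise ValueError(
            f"interval [{start}, {end}) outside {chrom} (length {seq_len})"
        )
    seq = str(fasta[key][start:end]).upper()
    n_valid = sum(1 for b in seq if b != "N")
    if n_valid == 0:
        return float("nan")
    gc = seq.count("G") + seq.count("C")
    return gc / n_valid


@dataclass
class BaitFeatures:
    """Per-bait genomic features used to characterise problematic regions.

    table columns: mappability, gc, rpkm_cv (NaN = missing),
    segdup_overlap (bool), segdup_fraction (overlap fraction of the bait).
    """

    table: pd.DataFrame  # indexed by bait_id


def _mean_track_over_baits(track: pd.DataFrame, baits: pd.DataFrame) -> pd.Series:
    """Length-weighted mean of a per-base score track over each bait.

    The track is bedGraph-style (piecewise constant). Baits with no
    covered base get NaN.
    """
    probe = baits[["chrom", "start", "end", "bait_id"]].rename(
        columns={"bait_id": "_bid"}
    )
    t = track.rename(columns={"score": "_score"})
    t["bait_id"] = [f"seg{i}" for i in range(len(t))]
    hits = baits_hit_many(probe, t[["chrom", "start", "end", "bait_id"]])
    if hits.empty:
        return pd.Series(np.nan, index=baits["bait_id"])
    seg = t.set_index("bait_id")
    seg_start = seg.loc[hits["bait_id"], "start"].to_numpy()
    seg_end = seg.loc[hits["bait_id"], "end"].to_numpy()
    seg_score = seg.loc[hits["bait_id"], "_score"].to_numpy()
    ov = np.minimum(hits["end"].to_numpy(), seg_end) - np.maximum(
        hits["start"].to_numpy(), seg_start
    )
    w = pd.DataFrame({"bid": hits["_bid"], "len": ov, "wscore": ov * seg_score})
    agg = w.groupby("bid").sum()
    mean = agg["wscore"] / agg["len"]
    return mean.reindex(baits["bait_id"])


def annotate(
    baits: pd.DataFrame,
    mappability: pd.DataFrame | pd.Series,
    segdups: pd.DataFrame,
    cv: pd.Series,
    fasta=None,
) -> BaitFeatures:
    """Assemble the per-bait feature table.

    mappability: bedGraph frame (per-base scores averaged over the bait)
        or a per-bait Series. Baits without coverage get NaN and are logged
        by the caller's report stage.
    segdups: BED frame; overlap of >= 1 bp sets segdup_overlap, and the
        covered fraction of the bait is retained.
    cv: per-bait RPKM CV from :func:`rpkm_cv`.
    fasta: optional sequence source; when given, per-bait GC is computed
        from it, otherwise a ``gc`` column on ``baits`` is used.
    """
    idx = pd.Index(baits["bait_id"], name="bait_id")
    out = pd.DataFrame(index=idx)

    if isinstance(mappability, pd.Series):
        out["mappability"] = mappability.reindex(idx)
    else:
        out["mappability"] = _mean_track_over_baits(mappability, baits).to_numpy()

    if fasta is not None:
        out["gc"] = [
            gc_content(c, int(s), int(e), fasta)
            for c, s, e in zip(baits["chrom"], baits["start"], baits["end"])
        ]
    elif "gc" in baits.columns:
        out["gc"] = baits["gc"].to_numpy()
    else:
        raise ValueError("no GC source: pass a FASTA or a gc column on baits")

    out["rpkm_cv"] = cv.reindex(idx)

    if len(segdups):
        sd = segdups[["chrom", "start", "end"]].copy()
        sd["bait_id"] = [f"sd{i}" for i in range(len(sd))]
        probe = baits[["chrom", "start", "end", "bait_id"]].rename(
            columns={"bait_id": "_bid"}
        )
        hits = baits_hit_many(probe, sd)
        if len(hits):
            sdi = sd.set_index("bait_id")
            ov = np.minimum(
                hits["end"].to_numpy(), sdi.loc[hits["bait_id"], "end"].to_numpy()
            ) - np.maximum(
                hits["start"].to_numpy(), sdi.loc[hits["bait_id"], "start"].to_numpy()
            )
            cov = pd.DataFrame({"bid": hits["_bid"], "ov": ov}).groupby("bid")["ov"].sum()
        else:
            cov = pd.Series(dtype=float)
    else:
        cov = pd.Series(dtype=float)
    blen = pd.Series((baits["end"] - baits["start"]).to_numpy(), index=idx)
    frac = (cov.reindex(idx).fillna(0) / blen).clip(upper=1.0)
    out["segdup_fraction"] = frac
    out["segdup_overlap"] = frac > 0
    return BaitFeatures(table=out)


@dataclass
class ComparisonResult:
    """Problematic-vs-random-non-problematic feature comparison.

    iterations: long frame ``iteration feature statistic p``.
    flagged_means / comparator_means: per-feature group means (comparator
    averaged over iterations).
    """

    n_iter: int
    seed: int
    iterations: pd.DataFrame
    flagged_means: pd.Series
    comparator_means: pd.Series

    def median_p(self) -> pd.Series:
        return self.iterations.groupby("feature")["p"].median()

    def significant_fraction(self, alpha: float = 0.05) -> pd.Series:
        return self.iterations.groupby("feature")["p"].apply(
            lambda p: float((p < alpha).mean())
        )

    def write(self, path: str | Path) -> None:
        self.iterations.to_csv(path, sep="\t", index=False)


def compare_features(
    features: BaitFeatures,
    mask: ProblematicMask,
    n_iter: int = 1000,
    seed: int = 0,
    features_to_test: tuple[str, ...] = FEATURES,
) -> ComparisonResult:
    """Wilcoxon rank-sum comparison of flagged baits vs random equal-size draws.

    Each iteration samples, without replacement, |flagged| baits from the
    non-problematic pool and runs a two-sided rank-sum test (normal
    approximation, continuity-corrected, average ranks for ties) per
    feature. Missing (NaN) feature values are excluded within each test.
    Fully reproducible from ``seed`` via per-iteration substreams.
    """
    if not mask.flagged_baits:
        raise ValueError("no problematic regions to compare")
    tab = features.table
    flagged_idx = tab.index.isin(mask.flagged_baits)
    flagged = tab[flagged_idx]
    pool = tab[~flagged_idx]
    if len(pool) < len(flagged):
        raise ValueError(
            f"non-problematic pool ({len(pool)}) smaller than flagged set ({len(flagged)})"
        )
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_iter)
    rows = []
    comp_sums = {f: 0.0 for f in features_to_test}
    k = len(flagged)
    pool_positions = np.arange(len(pool))
    for it in range(n_iter):
        rng = np.random.default_rng(streams[it])
        draw = pool.iloc[rng.choice(pool_positions, size=k, replace=False)]
        for feat in features_to_test:
            x = flagged[feat].dropna().to_numpy()
            y = draw[feat].dropna().to_numpy()
            if len(x) == 0 or len(y) == 0:
                stat, p = np.nan, np.nan
            else:
                res = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic"
                )
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append((it, feat, stat, p))
            comp_sums[feat] += float(np.nanmean(draw[feat].to_numpy()))
    iterations = pd.DataFrame(rows, columns=["iteration", "feature", "statistic", "p"])
    flagged_means = pd.Series(
        {f: float(np.nanmean(flagged[f].to_numpy())) for f in features_to_test}
    )
    comparator_means = pd.Series({f: comp_sums[f] / n_iter for f in features_to_test})
    return ComparisonResult(
        n_iter=n_iter,
        seed=seed,
        iterations=iterations,
        flagged_means=flagged_means,
        comparator_means=comparator_means,
    )
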