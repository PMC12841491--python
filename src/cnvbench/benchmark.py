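"""Exon(bait)-level classification of caller CNV calls against a truth set.

Every (sample, bait) unit is classified once per caller: a truth bait
covered by at least one qualifying call is a true positive, an uncovered
truth bait a false negative, and a called bait absent from that sample's
truth a false positive. True negatives are never enumerated — specificity
is not a reported metric at this unit of evaluation. Duplicate calls at
one bait collapse to one unit.

``type_aware`` (default True) demands DEL/DUP agreement between call and
truth: a DEL call at a DUP truth bait is simultaneously a false positive
and leaves the truth unit a false negative. The combined mode
(type_aware=False) matches on position alone and is provided for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import baits_hit_many
from .truth import TruthExonSet

__all__ = [
    "ExonClassification", "BenchmarkResult", "classify", "metrics",
    "concordance", "size_stratify",
]

SIZE_STRATA = ((0, 100_000, "<100kb"), (100_000, 500_000, "100-500kb"),
               (500_000, None, ">500kb"))


def size_stratify(cnvs: pd.DataFrame) -> pd.DataFrame:
    """Attach the conventional CNV size class (<100 kb, 100-500 kb, >500 kb).

    A report option for stratified summaries of event-level tables
    (e.g. the truth CNVs); operates on any ``start``/``end`` frame.
    """
    out = cnvs.copy()
    length = out["end"] - out["start"]
    labels = pd.Series("", index=out.index, dtype=object)
    for lo, hi, name in SIZE_STRATA:
        sel = (length > lo) & (length <= hi if hi is not None else True)
        if lo == 0:
            sel = (length <= hi)
        labels[sel] = name
    out["size_class"] = labels
    return out


@dataclass
class ExonClassification:
    """Per-(sample, bait) labels for one caller against one truth set.

    units: frame ``sample bait_id label call_type truth_type`` with label in
        {TP, FP, FN}; call_type is empty for FN rows, truth_type for FP rows.
    """

    caller_id: str
    type_aware: bool
    units: pd.DataFrame
    truth: TruthExonSet

    @property
    def tp(self) -> int:
        return int((self.units["label"] == "TP").sum())

    @property
    def fp(self) -> int:
        return int((self.units["label"] == "FP").sum())

    @property
    def fn(self) -> int:
        return int((self.units["label"] == "FN").sum())

    def per_sample_counts(self) -> pd.DataFrame:
        """Frame indexed by sample with tp/fp/fn columns (0-filled)."""
        tab = (
            self.units.groupby(["sample", "label"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        for c in ("TP", "FP", "FN"):
            if c not in tab.columns:
                tab[c] = 0
        return tab[["TP", "FP", "FN"]].rename(
            columns={"TP": "tp", "FP": "fp", "FN": "fn"}
        )

    def write(self, path) -> None:
        out = self.units.copy()
        out.insert(2, "caller", self.caller_id)
        out.sort_values(["sample", "bait_id", "label"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class BenchmarkResult:
    """TP/FP/FN counts and derived metrics for one caller and condition.

    sensitivity = TP / (TP + FN); ppv = TP / (TP + FP), ``None`` when no
    positive calls exist (undefined, never coerced to 0). The truth
    denominator is TP + FN by construction.
    """

    caller_id: str
    condition: str  # "pre" or "post"
    tp: int
    fp: int
    fn: int

    @property
    def truth_denominator(self) -> int:
        return self.tp + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None


def classify(
    calls: pd.DataFrame,
    truth: TruthExonSet,
    baits: pd.DataFrame,
    type_aware: bool = True,
    roster: list[str] | None = None,
) -> ExonClassification:
    """Label every (sample, bait) unit of one caller's calls as TP/FP/FN.

    ``roster`` is the evaluation cohort (defaults to the samples carrying
    truth labels); calls from samples outside it raise, and roster samples
    without calls still contribute their truth units as FN.
    """
    if roster is None:
        roster = sorted(truth.entries["sample"].unique())
    roster_set = set(roster)
    unknown = sorted(set(calls["sample"].unique()) - roster_set)
    if unknown:
        raise ValueError(f"calls from samples outside the cohort roster: {unknown}")
    callers = calls["caller"].unique() if len(calls) else []
    if len(callers) > 1:
        raise ValueError(f"classify expects one caller's calls, got {list(callers)}")
    caller_id = str(callers[0]) if len(callers) else "none"

    truth_units = truth.entries[truth.entries["sample"].isin(roster_set)]
    if len(calls):
        hits = baits_hit_many(calls, baits)
        call_units = (
            hits[["sample", "bait_id", "type"]]
            .drop_duplicates()
            .rename(columns={"type": "call_type"})
        )
    else:
        call_units = pd.DataFrame(columns=["sample", "bait_id", "call_type"])

    if type_aware:
        t = truth_units.rename(columns={"truth_type": "match_type"})
        c = call_units.rename(columns={"call_type": "match_type"})
    else:
        # position-only matching: one unit per (sample, bait)
        t = truth_units.drop_duplicates(["sample", "bait_id"]).assign(match_type="ANY")
        c = call_units.drop_duplicates(["sample", "bait_id"]).assign(match_type="ANY")

    key = ["sample", "bait_id", "match_type"]
    merged = t[key].merge(c[key], on=key, how="outer", indicator=True)

    truth_type_map = truth_units.set_index(["sample", "bait_id"])["truth_type"]
    truth_type_map = truth_type_map[~truth_type_map.index.duplicated()]
    call_type_map = call_units.set_index(["sample", "bait_id"])["call_type"]
    call_type_map = call_type_map[~call_type_map.index.duplicated()]

    label = merged["_merge"].map(
        {"both": "TP", "left_only": "FN", "right_only": "FP"}
    ).astype(str)
    units = merged[["sample", "bait_id"]].copy()
    units["label"] = label
    if type_aware:
        units["truth_type"] = merged["match_type"].where(label != "FP", "")
        units["call_type"] = merged["match_type"].where(label != "FN", "")
    else:
        idx = list(zip(units["sample"], units["bait_id"]))
        units["truth_type"] = [
            truth_type_map.get(k, "") if l != "FP" else "" for k, l in zip(idx, label)
        ]
        units["call_type"] = [
            call_type_map.get(k, "") if l != "FN" else "" for k, l in zip(idx, label)
        ]
    units = units[["sample", "bait_id", "label", "call_type", "truth_type"]]
    units = units.sort_values(["sample", "bait_id", "label"]).reset_index(drop=True)
    return ExonClassification(
        caller_id=caller_id, type_aware=type_aware, units=units, truth=truth
    )


def metrics(cls: ExonClassification, condition: str = "pre") -> BenchmarkResult:
    """Reduce a classification to counts, sensitivity and PPV."""
    return BenchmarkResult(
        caller_id=cls.caller_id, condition=condition,
        tp=cls.tp, fp=cls.fp, fn=cls.fn,
    )


def concordance(classifications: list[ExonClassification]) -> dict:
    """Cross-caller agreement on true-positive truth units.

    Returns per-exon detector sets, per-caller specific/shared fractions of
    its TP units, per-caller sensitivity and the union sensitivity (the
    sensitivity of the per-exon OR across callers). All classifications
    must share one truth set.
    """
    if not classifications:
        raise ValueError("need at least one classification")
    ref = classifications[0].truth
    for c in classifications[1:]:
        if c.truth.units() != ref.units():
            raise ValueError("classifications do not share one truth set")

    tp_sets = {
        c.caller_id: set(
            zip(
                c.units.loc[c.units["label"] == "TP", "sample"],
                c.units.loc[c.units["label"] == "TP", "bait_id"],
            )
        )
        for c in classifications
    }
    detected_by: dict[tuple[str, str], set[str]] = {}
    for caller, units in tp_sets.items():
        for u in units:
            detected_by.setdefault(u, set()).add(caller)

    denom = len(ref.entries.drop_duplicates(["sample", "bait_id"]))
    per_caller = {}
    for c in classifications:
        mine = tp_sets[c.caller_id]
        specific = sum(1 for u in mine if len(detected_by[u]) == 1)
        per_caller[c.caller_id] = {
            "tp": len(mine),
            "sensitivity": len(mine) / denom if denom else None,
            "specific_fraction": specific / len(mine) if mine else None,
            "shared_fraction": 1 - specific / len(mine) if mine else None,
        }
    union_tp = len(detected_by)
    return {
        "per_exon": detected_by,
        "per_caller": per_caller,
        "union_tp": union_tp,
        "union_sensitivity": union_tp / denom if denom else None,
        "truth_denominator": denom,
    }
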