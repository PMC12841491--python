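"""Apply a problematic-region mask and re-benchmark.

Masking removes every (sample, bait) unit at a flagged bait from the
calls AND from the truth denominator — the flagged baits are unreliable
for that caller in either direction, so they leave the evaluation
entirely (each caller's own mask shrinks its own truth denominator).
Per-sample pre/post count changes are tested with a two-sided Wilcoxon
signed-rank test; sensitivity may rise after masking only through
denominator reduction, never through invented true positives.

A whole-call removal mode (drop a CNV event entirely when it overlaps the
mask, keep the truth denominator fixed) is available through
``apply_mask_to_calls`` for workflows that filter call lists rather than
re-benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import BenchmarkResult, ExonClassification, metrics
from .intervals import baits_hit_many
from .problematic import ProblematicMask

__all__ = ["FilterOutcome", "apply_mask", "apply_mask_to_calls", "paired_test", "summarize"]

NOT_TESTABLE = "not testable"


@dataclass
class FilterOutcome:
    """Pre/post benchmark results and per-sample paired tests for one caller."""

    caller_id: str
    pre: BenchmarkResult
    post: BenchmarkResult
    per_sample: pd.DataFrame  # sample-indexed tp/fp/fn pre and post
    tests: dict  # statistic -> {"p": float | NOT_TESTABLE, "direction": str, "n": int}


def apply_mask(
    cls: ExonClassification,
    mask: ProblematicMask,
    baits: pd.DataFrame | None = None,
) -> ExonClassification:
    """Drop every unit whose bait is flagged; counts recompute on survivors.

    When ``baits`` (the evaluated kit) is given, mask entries outside it
    raise — they signal a mask built against a different bait set.
    """
    if baits is not None:
        unknown = mask.flagged_baits - set(baits["bait_id"])
        if unknown:
            raise ValueError(
                f"mask references unknown baits, e.g. {sorted(unknown)[:5]}"
            )
    surviving = cls.units[~cls.units["bait_id"].isin(mask.flagged_baits)].reset_index(
        drop=True
    )
    truth = cls.truth
    pruned_truth = type(truth)(
        entries=truth.entries[
            ~truth.entries["bait_id"].isin(mask.flagged_baits)
        ].reset_index(drop=True),
        n_cnvs=truth.n_cnvs,
        n_samples=truth.n_samples,
    )
    return ExonClassification(
        caller_id=cls.caller_id,
        type_aware=cls.type_aware,
        units=surviving,
        truth=pruned_truth,
    )


def apply_mask_to_calls(
    calls: pd.DataFrame, mask: ProblematicMask, baits: pd.DataFrame
) -> pd.DataFrame:
    """Whole-call removal mode: drop any call overlapping a flagged bait."""
    if not mask.flagged_baits:
        return calls.copy()
    flagged = baits[baits["bait_id"].isin(mask.flagged_baits)]
    probe = calls.reset_index().rename(columns={"index": "_row"})
    hits = baits_hit_many(probe, flagged)
    drop = set(hits["_row"])
    return calls[~calls.reset_index(drop=True).index.isin(drop)].reset_index(drop=True)


def paired_test(
    pre: pd.Series, post: pd.Series, statistic: str = "fp"
) -> dict:
    """Two-sided Wilcoxon signed-rank test on per-sample count differences.

    Zero differences are dropped (standard convention). Fewer than two
    non-zero differences is reported as not testable rather than forced
    into a p-value. Exact distribution for up to 25 non-zero differences,
    normal approximation with continuity correction above.
    """
    if not pre.index.equals(post.index):
        post = post.reindex(pre.index)
        if post.isna().any():
            raise ValueError("pre and post must cover the same sample roster")
    diff = (post - pre).astype(float)
    nz = diff[diff != 0]
    med = float(np.median(diff))
    direction = "decrease" if med < 0 else ("increase" if med > 0 else "none")
    if len(nz) < 2:
        return {"statistic": statistic, "p": NOT_TESTABLE, "direction": direction, "n": int(len(nz))}
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(
        nz.to_numpy(), zero_method="wilcox", correction=True,
        alternative="two-sided", method=method,
    )
    direction = "decrease" if nz.mean() < 0 else "increase"
    return {
        "statistic": statistic,
        "p": float(res.pvalue),
        "direction": direction,
        "n": int(len(nz)),
    }


def build_outcome(
    pre_cls: ExonClassification, post_cls: ExonClassification
) -> FilterOutcome:
    """Assemble the pre/post comparison for one caller."""
    pre_counts = pre_cls.per_sample_counts()
    post_counts = post_cls.per_sample_counts().reindex(pre_counts.index).fillna(0)
    per_sample = pre_counts.join(post_counts, lsuffix="_pre", rsuffix="_post").astype(int)
    tests = {
        "fp": paired_test(per_sample["fp_pre"], per_sample["fp_post"], "fp"),
        "tp": paired_test(per_sample["tp_pre"], per_sample["tp_post"], "tp"),
    }
    return FilterOutcome(
        caller_id=pre_cls.caller_id,
        pre=metrics(pre_cls, "pre"),
        post=metrics(post_cls, "post"),
        per_sample=per_sample,
        tests=tests,
    )


def _round3(x: float | None) -> float | None:
    """Half-even rounding to 3 decimals for report display."""
    if x is None:
        return None
    return float(np.round(x, 3))


def summarize(outcomes: list[FilterOutcome]) -> pd.DataFrame:
    """Report grid: TruthSet/TP/FP/FN/Sensitivity/PPV x {pre, post} per caller.

    Adds the sensitivity gain in percentage points and the PPV
    fold-change (post/pre; NaN-marked undefined when pre-PPV is 0 or
    either metric is undefined).
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    rows = []
    for o in outcomes:
        for cond, r in (("pre", o.pre), ("post", o.post)):
            rows.append(
                {
                    "caller": o.caller_id,
                    "condition": cond,
                    "truth_set": r.truth_denominator,
                    "tp": r.tp,
                    "fp": r.fp,
                    "fn": r.fn,
                    "sensitivity": _round3(r.sensitivity),
                    "ppv": _round3(r.ppv),
                }
            )
        sens_gain = (
            (o.post.sensitivity - o.pre.sensitivity) * 100
            if o.post.sensitivity is not None and o.pre.sensitivity is not None
            else np.nan
        )
        if o.pre.ppv and o.post.ppv is not None:
            ppv_fold = o.post.ppv / o.pre.ppv
        else:
            ppv_fold = np.nan
        rows.append(
            {
                "caller": o.caller_id,
                "condition": "delta",
                "truth_set": o.post.truth_denominator - o.pre.truth_denominator,
                "tp": o.post.tp - o.pre.tp,
                "fp": o.post.fp - o.pre.fp,
                "fn": o.post.fn - o.pre.fn,
                "sensitivity": round(sens_gain, 1) if np.isfinite(sens_gain) else np.nan,
                "ppv": round(ppv_fold, 2) if np.isfinite(ppv_fold) else np.nan,
            }
        )
    return pd.DataFrame(rows)
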