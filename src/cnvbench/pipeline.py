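"""End-to-end orchestration: truth -> benchmark -> mask -> filter -> report.

Each stage is a library call; this module sequences them, enforces the
cross-stage consistency checks, and writes the report bundle (Table-style
metric grid, per-caller mask BEDs, feature comparisons, and a
machine-readable run log carrying the seed, thresholds, package version
and input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .benchmark import classify, concordance, metrics
from .filtration import apply_mask, build_outcome, summarize
from .problematic import annotate, build_mask, compare_features, recurrence, rpkm, rpkm_cv
from .truth import TruthExonSet, TruthFilterConfig, expand_to_truth_exons, filter_array_cnvs

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and knobs of one pipeline run."""

    baits: Path
    array_cnvs: Path
    calls: dict[str, Path]  # caller -> call TSV
    depth_counts: Path
    depth_totals: Path
    mappability: Path
    segdups: Path
    outdir: Path
    fasta: Path | None = None
    cohort_size: int | None = None  # default: samples seen across call sets
    truth_filter: TruthFilterConfig = field(default_factory=TruthFilterConfig)
    mask_threshold: float = 0.10
    type_aware: bool = True
    n_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mask_threshold < 1):
            raise ValueError("mask threshold must be in (0, 1)")
        for name in ("baits", "array_cnvs", "depth_counts", "depth_totals",
                     "mappability", "segdups"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for caller, p in self.calls.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"calls[{caller}]: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("outdir")  # output location does not shape results
    d = {k: str(v) for k, v in d.items()}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage for the CLI."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def truth_consistency_check(truth: TruthExonSet) -> dict:
    """Report-layer identity: DEL exons + DUP exons == truth-set size."""
    by_type = truth.entries.groupby("truth_type").size().to_dict()
    n_del = int(by_type.get("DEL", 0))
    n_dup = int(by_type.get("DUP", 0))
    ok = n_del + n_dup == truth.n_exons
    if not ok:
        raise AssertionError(
            f"truth exon accounting broken: {n_del} DEL + {n_dup} DUP != {truth.n_exons}"
        )
    return {"del_exons": n_del, "dup_exons": n_dup, "total_exons": truth.n_exons}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle to cfg.outdir.

    Returns a dict with the in-memory results: truth set, per-caller
    classifications, masks, comparisons, filter outcomes and the summary
    grid.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {
        "package_version": __version__,
        "seed": cfg.seed,
        "mask_threshold": cfg.mask_threshold,
        "type_aware": cfg.type_aware,
        "n_iter": cfg.n_iter,
        "truth_filter": dataclasses.asdict(cfg.truth_filter),
        "config_hash": _config_hash(cfg),
        "input_checksums": {},
    }

    def _load(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - stage-named abort is the contract
            raise StageError(stage, e) from e

    baits = _load("inputs", cio.read_baits, cfg.baits)
    array = _load("inputs", cio.read_array_cnvs, cfg.array_cnvs)
    calls = {c: _load("inputs", cio.read_calls, p) for c, p in cfg.calls.items()}
    counts, totals = _load("inputs", cio.read_depth_matrix, cfg.depth_counts, cfg.depth_totals)
    mapp = _load("inputs", cio.read_bedgraph, cfg.mappability)
    segdups = _load("inputs", cio.read_bed, cfg.segdups)
    for name in ("baits", "array_cnvs", "depth_counts", "depth_totals",
                 "mappability", "segdups"):
        stamp["input_checksums"][name] = _sha256(Path(getattr(cfg, name)))
    for c, p in cfg.calls.items():
        stamp["input_checksums"][f"calls_{c}"] = _sha256(Path(p))

    cohort = sorted(set().union(*[set(df["sample"]) for df in calls.values()]))
    cohort_size = cfg.cohort_size or len(cohort)

    # --- truth set -------------------------------------------------------
    kept, audit = _load("truth", filter_array_cnvs, array, cfg.truth_filter, baits)
    truth = _load("truth", expand_to_truth_exons, kept, baits)
    consistency = truth_consistency_check(truth)
    audit.to_csv(out / "truth_audit.tsv", sep="\t", index=False)
    truth.write(baits, out / "truth_exons.tsv")
    roster = sorted(truth.entries["sample"].unique())

    # --- bait features ---------------------------------------------------
    rk = _load("features", rpkm, counts, totals, baits)
    cv = _load("features", rpkm_cv, rk)
    import pyfaidx

    fasta = pyfaidx.Fasta(str(cfg.fasta)) if cfg.fasta else None
    features = _load("features", annotate, baits, mapp, segdups, cv, fasta)
    n_nomap = int(features.table["mappability"].isna().sum())
    if n_nomap:
        log.warning("%d baits lack mappability coverage (set missing)", n_nomap)

    results: dict = {
        "truth": truth, "consistency": consistency, "audit": audit,
        "features": features, "pre": {}, "post": {}, "masks": {},
        "comparisons": {}, "outcomes": {},
    }

    outcomes = []
    for caller, df in calls.items():
        cohort_calls = df
        bench_calls = df[df["sample"].isin(roster)].reset_index(drop=True)
        pre_cls = _load(
            f"benchmark:{caller}", classify, bench_calls, truth, baits,
            cfg.type_aware, roster,
        )
        rec = _load(
            f"mask:{caller}", recurrence, cohort_calls, baits, cohort_size
        )
        mask = build_mask(rec, baits, cfg.mask_threshold)
        mask.write(out / f"mask_{caller}.bed", out / f"mask_{caller}_recurrence.tsv")
        if mask.flagged_baits:
            comp = _load(
                f"features:{caller}", compare_features, features, mask,
                cfg.n_iter, cfg.seed,
            )
            comp.write(out / f"feature_comparison_{caller}.tsv")
            results["comparisons"][caller] = comp
        post_cls = _load(f"filter:{caller}", apply_mask, pre_cls, mask, baits)
        outcome = build_outcome(pre_cls, post_cls)
        assert outcome.post.tp <= outcome.pre.tp
        assert outcome.post.fp <= outcome.pre.fp
        assert outcome.post.truth_denominator <= outcome.pre.truth_denominator
        assert outcome.post.tp + outcome.post.fn == outcome.post.truth_denominator
        outcomes.append(outcome)
        results["pre"][caller] = pre_cls
        results["post"][caller] = post_cls
        results["masks"][caller] = mask
        results["outcomes"][caller] = outcome
        outcome.per_sample.to_csv(out / f"per_sample_{caller}.tsv", sep="\t")

    grid = summarize(outcomes)
    grid.to_csv(out / "benchmark_grid.tsv", sep="\t", index=False)
    results["summary"] = grid
    conc = concordance(list(results["pre"].values()))
    results["concordance"] = conc
    pd.DataFrame(conc["per_caller"]).T.rename_axis("caller").reset_index().to_csv(
        out / "concordance.tsv", sep="\t", index=False
    )
    stamp["truth_consistency"] = consistency
    stamp["union_sensitivity"] = conc["union_sensitivity"]
    stamp["signed_rank"] = {
        o.caller_id: {k: v for k, v in o.tests.items()} for o in outcomes
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(stamp, sort_keys=False))
    # every output is tied to the inputs and config that produced it
    manifest_rows = [
        {"file": p.name, "sha256": _sha256(p), "config_hash": stamp["config_hash"]}
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "output_manifest.tsv"
    ]
    pd.DataFrame(manifest_rows).to_csv(out / "output_manifest.tsv", sep="\t", index=False)
    results["run_log"] = stamp
    return results
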