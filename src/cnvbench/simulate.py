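"""Seeded generator of a full synthetic exome-CNV benchmarking study.

The generator emulates the data structures of a clinical WES cohort with
an array-derived truth subset: a toy multi-chromosome genome, a capture
bait set, a per-base mappability track, segmental duplications, an
array-style CNV table (with SNP-probe counts and decoy records that
exercise every truth filter), per-caller call tables with planted
caller-specific artifact loci, and a bait x sample read-count matrix.

The statistical structure mirrors what the pipeline is built to detect:
planted artifact baits are called in a configurable fraction of the whole
cohort (default 0.30, well above the 0.10 masking threshold), sit in
neighbourhoods with depressed mappability and shifted GC, co-locate with
segmental duplications at a configurable probability (default 0.8) and
carry inflated inter-sample depth noise so their RPKM CV is elevated.
Caller profiles are caricatures of real exome CNV callers (per-exon
detection sensitivity, sporadic false-positive rate, artifact burden),
not emulations of the tools' algorithms.

Everything is driven by one seed through spawned substreams, so a fixed
configuration reproduces byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .intervals import baits_hit_many

__all__ = ["CallerProfile", "SimConfig", "SimBundle", "simulate", "emulate_caller"]


@dataclass(frozen=True)
class CallerProfile:
    """Caricature of one exome CNV caller.

    sensitivity: per-truth-exon detection probability.
    sporadic_fp_rate: per (non-artifact bait, sample) false-call probability.
    n_artifact_baits: caller-specific systematic artifact loci (one bait each).
    artifact_recurrence: per-sample calling probability at an artifact bait.
    """

    sensitivity: float
    sporadic_fp_rate: float
    n_artifact_baits: int
    artifact_recurrence: float = 0.30

    def __post_init__(self) -> None:
        for name in ("sensitivity", "sporadic_fp_rate", "artifact_recurrence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_artifact_baits < 0:
            raise ValueError("n_artifact_baits must be >= 0")


def default_profiles() -> dict[str, CallerProfile]:
    """Four caller caricatures spanning the observed behaviour space:

    a sensitive but artifact-heavy read-depth caller (exomedepth-like), a
    moderate one (cnvkit-like), a caller whose false positives are mostly
    sporadic rather than recurrent (conifer-like), and an insensitive
    caller with a heavy artifact share (cnmops-like).
    """
    return {
        "exomedepth": CallerProfile(0.76, 8e-4, 300),
        "cnvkit": CallerProfile(0.66, 1e-3, 150),
        "conifer": CallerProfile(0.77, 6e-4, 25),
        "cnmops": CallerProfile(0.17, 4e-4, 200),
    }


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the benchmarked study design: 180 sequenced
    samples of which 39 carry 98 surviving array-confirmed CNVs
    (39 deletions : 59 duplications), 20,000 capture baits, planted
    artifact recurrence 0.30 against a 0.10 masking threshold, and a 0.8
    segmental-duplication co-location probability for artifact baits.
    """

    n_samples: int = 180
    n_baits: int = 20_000
    n_chroms: int = 8
    chrom_length: int = 5_000_000
    bait_length: int = 120
    baited_fraction: float = 0.96  # leave each chromosome tail bait-free

    n_truth_samples: int = 39
    n_truth_del: int = 39
    n_truth_dup: int = 59
    truth_size_range: tuple[int, int] = (20_000, 150_000)  # log-uniform
    snp_probe_per_bp: float = 1 / 2000  # array probe density, floor 1

    # decoy array records exercising each truth filter
    n_lowprobe_decoys: int = 15
    decoy_size_range: tuple[int, int] = (5_000, 17_000)
    polymorphic_locus_samples: int = 6
    n_offtarget_decoys: int = 5
    n_manual_fail_decoys: int = 3

    profiles: dict[str, CallerProfile] = field(default_factory=default_profiles)

    # feature structure at artifact baits
    background_mappability: float = 0.92
    mappability_decrement: float = 0.40
    background_gc: float = 0.45
    artifact_gc_shift: float = -0.10
    cv_multiplier: float = 3.0
    background_depth_sigma: float = 0.15
    segdup_colocation: float = 0.8
    background_segdup_rate: float = 0.02

    mean_bait_reads: float = 200.0
    on_target_fraction: float = 0.6

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_truth_samples > self.n_samples:
            raise ValueError("n_truth_samples cannot exceed n_samples")
        if self.n_truth_del + self.n_truth_dup > 0 and self.n_truth_samples < 1:
            raise ValueError("truth CNVs require at least one truth sample")
        for p in self.profiles.values():
            if p.n_artifact_baits > self.n_baits:
                raise ValueError("artifact loci exceed bait count")
        for r in (
            self.baited_fraction, self.background_mappability, self.background_gc,
            self.segdup_colocation, self.background_segdup_rate, self.on_target_fraction,
        ):
            if not (0.0 < r <= 1.0):
                raise ValueError(f"rate {r} outside (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["profiles"] = {k: dataclasses.asdict(v) for k, v in self.profiles.items()}
        d["truth_size_range"] = list(self.truth_size_range)
        d["decoy_size_range"] = list(self.decoy_size_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "profiles" in d:
            d["profiles"] = {k: CallerProfile(**v) for k, v in d["profiles"].items()}
        for key in ("truth_size_range", "decoy_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimBundle:
    """All artefacts of one simulated study, mutually consistent.

    manifest holds the planted ground truth consumed by tests: the clean
    (filter-surviving) array CNVs, the expected per-(sample, bait, type)
    truth exons, and the artifact baits planted per caller.
    """

    config: SimConfig
    baits: pd.DataFrame  # chrom start end bait_id
    genome: dict[str, str]
    mappability: pd.DataFrame  # bedGraph frame
    segdups: pd.DataFrame  # chrom start end
    array_cnvs: pd.DataFrame  # 0-based in memory; includes decoys
    calls: dict[str, pd.DataFrame]
    depth_counts: pd.DataFrame
    depth_totals: pd.Series
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        self.config.to_yaml(out / "sim_config.yaml")
        paths["config"] = out / "sim_config.yaml"
        cio.write_baits(self.baits, out / "baits.bed")
        paths["baits"] = out / "baits.bed"
        cio.write_fasta(self.genome, out / "genome.fa")
        paths["genome"] = out / "genome.fa"
        cio.write_bedgraph(self.mappability, out / "mappability.bedgraph")
        paths["mappability"] = out / "mappability.bedgraph"
        cio.write_bed(self.segdups, out / "segdups.bed")
        paths["segdups"] = out / "segdups.bed"
        cio.write_array_cnvs(self.array_cnvs, out / "array_cnvs.tsv")
        paths["array_cnvs"] = out / "array_cnvs.tsv"
        for caller, df in self.calls.items():
            p = out / f"calls_{caller}.tsv"
            cio.write_calls(df, p)
            paths[f"calls_{caller}"] = p
        cio.write_depth_matrix(
            self.depth_counts, out / "depth_counts.tsv",
            self.depth_totals, out / "depth_totals.tsv",
        )
        paths["depth_counts"] = out / "depth_counts.tsv"
        paths["depth_totals"] = out / "depth_totals.tsv"
        self.manifest["truth_exons"].to_csv(out / "manifest_truth_exons.tsv", sep="\t", index=False)
        art = pd.DataFrame(
            [
                (caller, b)
                for caller, bs in self.manifest["artifact_baits"].items()
                for b in sorted(bs)
            ],
            columns=["caller", "bait_id"],
        )
        art.to_csv(out / "manifest_artifact_baits.tsv", sep="\t", index=False)
        paths["manifest_truth_exons"] = out / "manifest_truth_exons.tsv"
        paths["manifest_artifact_baits"] = out / "manifest_artifact_baits.tsv"
        return paths


# ---------------------------------------------------------------------------


def _build_baits(cfg: SimConfig) -> pd.DataFrame:
    per_chrom = [cfg.n_baits // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_baits % cfg.n_chroms):
        per_chrom[i] += 1
    rows = []
    for c in range(cfg.n_chroms):
        n = per_chrom[c]
        usable = int(cfg.chrom_length * cfg.baited_fraction)
        spacing = usable // max(n, 1)
        if spacing <= cfg.bait_length:
            raise ValueError("bait spacing would make baits overlap; lower n_baits")
        for i in range(n):
            s = i * spacing + spacing // 4
            rows.append((f"c{c + 1}", s, s + cfg.bait_length, f"b{c + 1}_{i:05d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "bait_id"])


def _place_disjoint(
    rng: np.random.Generator,
    cfg: SimConfig,
    sizes: list[int],
    occupied: list[tuple[str, int, int]],
    margin: int,
) -> list[tuple[str, int, int]]:
    """Place intervals of the given sizes in baited space, disjoint from
    ``occupied`` (with margin); appends placements to occupied."""
    usable = int(cfg.chrom_length * cfg.baited_fraction)
    placed = []
    for size in sizes:
        for _ in range(1000):
            chrom = f"c{rng.integers(1, cfg.n_chroms + 1)}"
            start = int(rng.integers(0, max(1, usable - size)))
            end = start + size
            clash = any(
                c == chrom and start < e + margin and s - margin < end
                for c, s, e in occupied
            )
            if not clash:
                occupied.append((chrom, start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise ValueError("could not place a CNV disjointly; genome too crowded")
    return placed


def _probe_count(cfg: SimConfig, length: int) -> int:
    return max(1, round(length * cfg.snp_probe_per_bp))


def _build_array_cnvs(
    rng: np.random.Generator, cfg: SimConfig, baits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Array CNV table (clean + decoys) and the clean subset."""
    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    truth_samples = list(rng.choice(samples, size=cfg.n_truth_samples, replace=False))
    occupied: list[tuple[str, int, int]] = []
    lo, hi = cfg.truth_size_range
    n_clean = cfg.n_truth_del + cfg.n_truth_dup
    sizes = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n_clean)
    ).astype(int).tolist()
    placements = _place_disjoint(rng, cfg, sizes, occupied, margin=5000)
    types = ["DEL"] * cfg.n_truth_del + ["DUP"] * cfg.n_truth_dup
    rng.shuffle(types)
    # every truth sample carries >= 1 event; remainder assigned at random
    owner = list(truth_samples)
    owner += list(rng.choice(truth_samples, size=n_clean - len(owner), replace=True))
    rng.shuffle(owner)
    clean_rows = [
        {
            "chrom": c, "start": s, "end": e, "type": t, "sample": o,
            "snp_probes": _probe_count(cfg, e - s), "manual_pass": True,
        }
        for (c, s, e), t, o in zip(placements, types, owner)
    ]

    decoy_rows = []
    dlo, dhi = cfg.decoy_size_range
    sizes = np.exp(
        rng.uniform(np.log(dlo), np.log(dhi), size=cfg.n_lowprobe_decoys)
    ).astype(int).tolist()
    for (c, s, e) in _place_disjoint(rng, cfg, sizes, occupied, margin=5000):
        decoy_rows.append(
            {
                "chrom": c, "start": s, "end": e,
                "type": rng.choice(["DEL", "DUP"]),
                "sample": rng.choice(samples),
                "snp_probes": _probe_count(cfg, e - s),
                "manual_pass": True,
            }
        )
    # one polymorphic locus shared by > max_polymorphic_samples samples
    if cfg.polymorphic_locus_samples:
        (c, s, e), = _place_disjoint(rng, cfg, [40_000], occupied, margin=5000)
        carriers = rng.choice(samples, size=cfg.polymorphic_locus_samples, replace=False)
        for sm in carriers:
            js, je = int(rng.integers(-2000, 2000)), int(rng.integers(-2000, 2000))
            decoy_rows.append(
                {
                    "chrom": c, "start": max(0, s + js), "end": e + je,
                    "type": rng.choice(["DEL", "DUP"]), "sample": sm,
                    "snp_probes": _probe_count(cfg, e - s), "manual_pass": True,
                }
            )
    # off-target decoys in the bait-free chromosome tails
    usable = int(cfg.chrom_length * cfg.baited_fraction)
    tail = cfg.chrom_length - usable
    if cfg.n_offtarget_decoys and tail < 4000:
        raise ValueError("chromosome tail too small for off-target decoys")
    for _ in range(cfg.n_offtarget_decoys):
        chrom = f"c{rng.integers(1, cfg.n_chroms + 1)}"
        size = int(rng.integers(2000, min(60_000, tail - 1500)))
        start = int(rng.integers(usable + 1000, cfg.chrom_length - size))
        decoy_rows.append(
            {
                "chrom": chrom, "start": start, "end": start + size,
                "type": rng.choice(["DEL", "DUP"]), "sample": rng.choice(samples),
                "snp_probes": _probe_count(cfg, size), "manual_pass": True,
            }
        )
    # manually rejected records (technical artifacts on array review)
    sizes = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=cfg.n_manual_fail_decoys)
    ).astype(int).tolist()
    for (c, s, e) in _place_disjoint(rng, cfg, sizes, occupied, margin=5000):
        decoy_rows.append(
            {
                "chrom": c, "start": s, "end": e,
                "type": rng.choice(["DEL", "DUP"]), "sample": rng.choice(samples),
                "snp_probes": _probe_count(cfg, e - s), "manual_pass": False,
            }
        )

    clean = pd.DataFrame(clean_rows)
    all_rows = pd.DataFrame(clean_rows + decoy_rows)
    all_rows = cio.sort_genomic(all_rows)
    return all_rows, cio.sort_genomic(clean)


def _plant_artifacts(
    rng: np.random.Generator, cfg: SimConfig, baits: pd.DataFrame,
    truth_exons: pd.DataFrame,
) -> dict[str, set[str]]:
    """Choose caller-specific artifact baits, avoiding truth exons so that
    planted-artifact recovery is unambiguous."""
    truth_bait_ids = set(truth_exons["bait_id"])
    free = baits.loc[~baits["bait_id"].isin(truth_bait_ids), "bait_id"].to_numpy()
    out: dict[str, set[str]] = {}
    for caller, prof in cfg.profiles.items():
        if prof.n_artifact_baits > len(free):
            raise ValueError("artifact loci exceed available non-truth baits")
        out[caller] = set(rng.choice(free, size=prof.n_artifact_baits, replace=False))
    return out


def _build_genome(
    rng: np.random.Generator, cfg: SimConfig, baits: pd.DataFrame,
    artifact_union: set[str],
) -> dict[str, str]:
    """i.i.d. base composition at background_gc, with GC-shifted windows
    (bait +/- 500 bp) around artifact baits so gc_content has signal."""
    genome: dict[str, np.ndarray] = {}
    letters = np.frombuffer(b"ACGT", dtype="S1")

    def draw(n: int, gc: float) -> np.ndarray:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return letters[rng.choice(4, size=n, p=p)]

    for c in range(1, cfg.n_chroms + 1):
        genome[f"c{c}"] = draw(cfg.chrom_length, cfg.background_gc)
    art = baits[baits["bait_id"].isin(artifact_union)]
    gc_art = float(np.clip(cfg.background_gc + cfg.artifact_gc_shift, 0.05, 0.95))
    for chrom, s, e in zip(art["chrom"], art["start"], art["end"]):
        lo = max(0, int(s) - 500)
        hi = min(cfg.chrom_length, int(e) + 500)
        genome[chrom][lo:hi] = draw(hi - lo, gc_art)
    return {k: v.tobytes().decode("ascii") for k, v in genome.items()}


def _build_mappability(
    rng: np.random.Generator, cfg: SimConfig, baits: pd.DataFrame,
    artifact_union: set[str],
) -> pd.DataFrame:
    """Piecewise-constant uniqueness track: 2 kb background blocks near
    background_mappability, depressed blocks spanning artifact baits."""
    block = 2000
    rows = []
    art = baits[baits["bait_id"].isin(artifact_union)]
    art_by_chrom = {
        c: list(zip(g["start"], g["end"])) for c, g in art.groupby("chrom")
    }
    for c in range(1, cfg.n_chroms + 1):
        chrom = f"c{c}"
        n_blocks = int(np.ceil(cfg.chrom_length / block))
        scores = np.clip(
            rng.normal(cfg.background_mappability, 0.04, size=n_blocks), 0.0, 1.0
        )
        starts = np.arange(n_blocks) * block
        ends = np.minimum(starts + block, cfg.chrom_length)
        for s, e in art_by_chrom.get(chrom, []):
            b0, b1 = int(s) // block, (int(e) - 1) // block
            lowered = scores[b0 : b1 + 1] - cfg.mappability_decrement
            scores[b0 : b1 + 1] = np.clip(
                lowered + rng.normal(0, 0.03, size=b1 - b0 + 1), 0.0, 1.0
            )
        for s, e, sc in zip(starts, ends, scores):
            rows.append((chrom, int(s), int(e), round(float(sc), 4)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def _build_segdups(
    rng: np.random.Generator, cfg: SimConfig, baits: pd.DataFrame,
    artifact_union: set[str],
) -> pd.DataFrame:
    rows = []
    art = baits["bait_id"].isin(artifact_union)
    for _, b in baits[art].iterrows():
        if rng.random() < cfg.segdup_colocation:
            pad = int(rng.integers(200, 2000))
            rows.append((b["chrom"], max(0, b["start"] - pad), b["end"] + pad))
    n_bg = int(cfg.background_segdup_rate * (~art).sum())
    bg = baits[~art].sample(n=n_bg, random_state=int(rng.integers(2**31)))
    for _, b in bg.iterrows():
        pad = int(rng.integers(200, 2000))
        rows.append((b["chrom"], max(0, b["start"] - pad), b["end"] + pad))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return cio.sort_genomic(df) if len(df) else df


def _build_depth(
    rng: np.random.Generator, cfg: SimConfig, baits: pd.DataFrame,
    artifact_union: set[str],
) -> tuple[pd.DataFrame, pd.Series]:
    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    n_b, n_s = len(baits), cfg.n_samples
    mu = rng.lognormal(np.log(cfg.mean_bait_reads), 0.5, size=n_b)
    f = rng.lognormal(0.0, 0.2, size=n_s)
    sigma = np.full(n_b, cfg.background_depth_sigma)
    sigma[baits["bait_id"].isin(artifact_union).to_numpy()] *= cfg.cv_multiplier
    noise = rng.lognormal(0.0, sigma[:, None], size=(n_b, n_s))
    lam = mu[:, None] * f[None, :] * noise
    counts = rng.poisson(lam).astype(np.int64)
    m = pd.DataFrame(counts, index=pd.Index(baits["bait_id"], name="bait_id"), columns=samples)
    totals = pd.Series(
        (m.sum(axis=0) / cfg.on_target_fraction).round().astype(np.int64),
        name="total_mapped_reads",
    )
    return m, totals


def _segments_from_baits(sub: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Merge runs of positionally consecutive detected baits into segments.

    Only baits adjacent in kit order merge, so a segment never spans an
    undetected bait — per-exon detection stays exactly Bernoulli.
    """
    if sub.empty:
        return []
    sub = sub.sort_values("_pos")
    pos = sub["_pos"].to_numpy()
    chrom = sub["chrom"].to_numpy()
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    brk = np.nonzero((np.diff(pos) != 1) | (chrom[1:] != chrom[:-1]))[0] + 1
    segs = []
    for idx in np.split(np.arange(len(sub)), brk):
        segs.append((chrom[idx[0]], int(starts[idx[0]]), int(ends[idx[-1]])))
    return segs


def emulate_caller(
    caller: str,
    profile: CallerProfile,
    clean_cnvs: pd.DataFrame,
    truth_exons: pd.DataFrame,
    artifact_baits: set[str],
    baits: pd.DataFrame,
    samples: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate one caller's call table.

    Truth exons are detected per-bait with probability ``sensitivity``
    (consecutive detections merge into segments); each artifact bait is
    called per sample with probability ``artifact_recurrence``; sporadic
    false positives land uniformly on the remaining baits at
    ``sporadic_fp_rate`` per (bait, sample). Call types: truth-derived
    calls inherit the event type, artifact and sporadic calls draw
    DEL/DUP at random.
    """
    rows: list[tuple] = []
    indexed = baits.reset_index(drop=True).copy()
    indexed["_pos"] = np.arange(len(indexed))

    # truth-derived detections
    by_bait = truth_exons.merge(
        indexed[["bait_id", "chrom", "start", "end", "_pos"]], on="bait_id"
    )
    for (sample, ttype), grp in by_bait.groupby(["sample", "truth_type"]):
        det = grp[rng.random(len(grp)) < profile.sensitivity]
        for chrom, s, e in _segments_from_baits(det):
            rows.append((chrom, s, e, ttype, sample, caller))

    def _bernoulli_calls(sub: pd.DataFrame, rate: float) -> None:
        if sub.empty or rate <= 0:
            return
        hitmat = rng.random((len(sub), len(samples))) < rate
        types = np.where(rng.random((len(sub), len(samples))) < 0.5, "DEL", "DUP")
        chrom = sub["chrom"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        sarr = np.asarray(samples)
        bi, si = np.nonzero(hitmat)
        rows.extend(
            zip(
                chrom[bi], starts[bi].tolist(), ends[bi].tolist(),
                types[bi, si], sarr[si], [caller] * len(bi),
            )
        )

    # recurrent artifact calls, then sporadic FPs on the remaining baits
    art_mask = indexed["bait_id"].isin(artifact_baits)
    _bernoulli_calls(
        indexed[art_mask].sort_values("bait_id"), profile.artifact_recurrence
    )
    _bernoulli_calls(indexed[~art_mask], profile.sporadic_fp_rate)

    df = pd.DataFrame(rows, columns=cio.CALL_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return cio.sort_genomic(df)


def simulate(cfg: SimConfig) -> SimBundle:
    """Generate the full synthetic study bundle for one configuration."""
    root = np.random.SeedSequence(cfg.seed)
    keys = (
        "array", "artifacts", "genome", "mappability", "segdups", "depth", "callers"
    )
    streams = dict(zip(keys, root.spawn(len(keys))))

    baits = _build_baits(cfg)
    array_cnvs, clean = _build_array_cnvs(
        np.random.default_rng(streams["array"]), cfg, baits
    )
    truth_exons = (
        baits_hit_many(clean, baits)[["sample", "bait_id", "type"]]
        .drop_duplicates()
        .rename(columns={"type": "truth_type"})
        .sort_values(["sample", "bait_id"])
        .reset_index(drop=True)
    )
    artifact_baits = _plant_artifacts(
        np.random.default_rng(streams["artifacts"]), cfg, baits, truth_exons
    )
    artifact_union = set().union(*artifact_baits.values()) if artifact_baits else set()

    genome = _build_genome(
        np.random.default_rng(streams["genome"]), cfg, baits, artifact_union
    )
    mappability = _build_mappability(
        np.random.default_rng(streams["mappability"]), cfg, baits, artifact_union
    )
    segdups = _build_segdups(
        np.random.default_rng(streams["segdups"]), cfg, baits, artifact_union
    )
    depth_counts, depth_totals = _build_depth(
        np.random.default_rng(streams["depth"]), cfg, baits, artifact_union
    )

    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    caller_streams = streams["callers"].spawn(len(cfg.profiles))
    calls = {
        caller: emulate_caller(
            caller, prof, clean, truth_exons, artifact_baits[caller],
            baits, samples, np.random.default_rng(ss),
        )
        for (caller, prof), ss in zip(cfg.profiles.items(), caller_streams)
    }

    manifest = {
        "clean_cnvs": clean,
        "truth_exons": truth_exons,
        "artifact_baits": artifact_baits,
        "samples": samples,
        "truth_samples": sorted(clean["sample"].unique()),
    }
    return SimBundle(
        config=cfg, baits=baits, genome=genome, mappability=mappability,
        segdups=segdups, array_cnvs=array_cnvs, calls=calls,
        depth_counts=depth_counts, depth_totals=depth_totals, manifest=manifest,
    )
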