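# cnvbench

Benchmarking exome-sequencing CNV callers at the exon level, and cleaning up
their output by masking caller-specific *problematic regions*.

CNV detection from whole-exome sequencing (WES) read depth is notoriously
noisy: every caller has loci it calls over and over again across unrelated
samples, and those recurrent artifacts dominate its false-positive burden.
`cnvbench` is for groups who run WES CNV callers (ExomeDepth, CNVkit,
CoNIFER, cn.MOPS, ...) on a cohort and want to (1) measure each caller's
sensitivity and positive predictive value against an orthogonal
array-derived truth set, (2) locate each caller's systematic-artifact
regions from cohort recurrence alone, and (3) quantify how much masking
those regions improves the caller's precision.

## The method

**Unit of evaluation.** Everything is counted per capture bait (used
interchangeably with "exon"): a truth CNV or a call is expanded to the set
of baits it overlaps by ≥ 1 bp (0-based half-open coordinates throughout).

**Truth set.** Array (CMA-style) CNVs pass a filter cascade — optional
manual-review flag, ≥ 10 SNP probes, exclusion of highly polymorphic loci
(merged CNV loci carried by > 4 distinct samples), overlap with ≥ 1 bait —
and survivors become per-(sample, bait) truth labels.

**Benchmark.** For each caller and sample, a truth bait covered by a call
of matching type is a true positive, an uncovered truth bait a false
negative, and a called bait absent from that sample's truth a false
positive:

    Sensitivity = TP / (TP + FN)        PPV = TP / (TP + FP)

**Problematic regions.** For each caller, a bait called (DEL or DUP) in
strictly more than 10% of the *whole* cohort — not just the truth-positive
samples — is flagged; flagged baits merge into reportable regions. Flagged
baits are characterised against 1000 equal-size random draws from the
non-problematic baits with two-sided Wilcoxon rank-sum tests on
mappability (mean 35-mer uniqueness), GC content and inter-sample RPKM
coefficient of variation (sd/mean, n−1), with segmental-duplication
overlap tracked alongside.

**Filtration.** Masking removes flagged (sample, bait) units from the
calls *and* from the truth denominator, metrics are recomputed, and the
per-sample pre/post changes in TP and FP counts are tested with a
two-sided Wilcoxon signed-rank test (zeros dropped).

A seeded synthetic-study generator (`cnvbench.simulate`) produces a full
mutually consistent bundle — toy genome, baits, mappability track,
segmental duplications, array CNV table with decoys for every filter,
per-caller call sets with planted artifact loci, and a depth matrix with
inflated variance at artifact baits — so the whole pipeline is testable
with known ground truth.

## Worked example

```python
import cnvbench as cb

cfg = cb.SimConfig(
    n_samples=60, n_baits=3000, n_chroms=3, chrom_length=2_500_000,
    n_truth_samples=12, n_truth_del=8, n_truth_dup=10,
    truth_size_range=(20_000, 60_000),
    profiles={"depthcaller": cb.CallerProfile(0.8, 1e-3, 40)},
    seed=11,
)
bundle = cb.simulate(cfg)

kept, audit = cb.filter_array_cnvs(bundle.array_cnvs, cb.TruthFilterConfig(), bundle.baits)
truth = cb.expand_to_truth_exons(kept, bundle.baits)

roster = sorted(truth.entries["sample"].unique())
calls = bundle.calls["depthcaller"]
pre = cb.classify(calls[calls["sample"].isin(roster)], truth, bundle.baits, roster=roster)

rec = cb.recurrence(calls, bundle.baits, cohort_size=cfg.n_samples)
mask = cb.build_mask(rec, bundle.baits, threshold=0.10)
post = cb.apply_mask(pre, mask, bundle.baits)
outcome = cb.build_outcome(pre, post)
print(cb.summarize([outcome]).to_string(index=False))
```

prints

```
     caller condition  truth_set  tp   fp  fn  sensitivity   ppv
depthcaller       pre        255 201  165  54        0.788 0.549
depthcaller      post        255 201   26  54        0.788 0.885
depthcaller     delta          0   0 -139   0        0.000 1.610
```

The simulated caller detects 201 of the 255 truth exons (sensitivity
0.788). Its 40 planted artifact baits — each called in ~30% of the
60-sample cohort — are all recovered by the 10% recurrence threshold;
masking them removes 139 of 165 false-positive units while touching no
true positives, lifting PPV from 0.549 to 0.885 (a 1.61-fold change). The
per-sample false-positive drop is significant under the signed-rank test
(p ≈ 5 × 10⁻⁴, n = 12 changed samples).

The same workflow is available from the shell:

```bash
cnvbench simulate --seed 11 --out bundle/
cnvbench run --baits bundle/baits.bed --array bundle/array_cnvs.tsv \
    --calls depthcaller bundle/calls_depthcaller.tsv \
    --depth-counts bundle/depth_counts.tsv --depth-totals bundle/depth_totals.tsv \
    --mappability bundle/mappability.bedgraph --segdups bundle/segdups.bed \
    --fasta bundle/genome.fa --out report/
```

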