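# Methods

## Coordinate system and interval arithmetic

All intervals are 0-based half-open (BED convention). Array CNV tables,
conventionally 1-based inclusive, are converted at the reader boundary
(`start − 1`, `end` unchanged) and never seen downstream in 1-based form.
Overlap means ≥ 1 shared base under half-open semantics; a configurable
minimum-reciprocal-overlap knob exists in spirit everywhere "overlap" is
used but every default is the permissive ≥ 1 bp reading, because bait-level
expansion makes stricter reciprocal criteria redundant (a 150 bp bait inside
a 100 kb CNV can never satisfy a reciprocal threshold). Merging uses
union-of-covered-bases semantics: with `gap=0`, book-ended intervals
([0,10) + [10,20)) merge, so merging never changes the covered base set and
is idempotent. Strand is ignored; a leading `chr` is stripped for
chromosome comparison and mixed dialects are unified with a log message.

The interval primitives are implemented directly on sorted numpy arrays
(per-chromosome binary search with a running-maximum bound on interval
ends, so overlapping baits are handled); the test suite checks them
against per-base enumeration oracles and against pyranges.

## Truth-set construction

The filter cascade evaluates, in fixed order: manual-review flag (only
when the input carries a `manual_pass` column; the review itself is not
automated), SNP-probe support (reject < 10 probes), polymorphic-locus
exclusion, bait overlap. The audit file records exactly the first failing
rule per record so reruns are byte-identical.

"Within a highly polymorphic region" is operationalised as: merge *all*
input CNVs across samples at gap 0; a merged locus is polymorphic when
CNVs from more than 4 distinct samples overlap it; every CNV overlapping
such a locus is rejected. Locus counting uses the full input table (i.e.
before the probe filter removes records): the alternative orderings are
defensible, but counting carriers on the unfiltered table is the reading
that does not let a genotyping-support threshold hide population-level
polymorphism.

Truth labels are kept per (sample, bait, type). A DEL in one sample and a
DUP in another at the same bait therefore never conflict — evaluation is
always within-sample — and a bait covered by two same-sample CNVs of one
type counts once.

## Benchmarking

The capture bait is the atomic unit; one bait = one countable unit per
sample. `type_aware=True` (default) requires DEL/DUP agreement for a true
positive, so a DEL call at a DUP truth bait is simultaneously a false
positive and leaves a false negative; the position-only mode is available
for sensitivity analyses. True negatives are never enumerated — there is
no meaningful bait-level specificity denominator for rare CNVs. Samples in
the evaluation roster with truth labels but no calls contribute false
negatives; calls from samples outside the roster are an error, not a
silent drop. PPV with zero positive calls is reported as undefined
(`None`), never coerced to 0. Display rounding is half-even to 3 decimals;
raw fractions are retained internally.

Cross-caller concordance reduces each caller's true-positive units to
(sample, bait) pairs; the union sensitivity is the sensitivity of the
per-exon OR across callers, and each caller's "specific fraction" is the
share of its TP units no other caller detected.

## Problematic regions

Recurrence is counted per bait as the number of *distinct* samples with at
least one overlapping call (DEL and DUP pooled; a type-split mode exists),
divided by the full cohort size — all sequenced samples, not only the
truth-positive subset. A bait is flagged when its fraction strictly
exceeds the threshold (default 0.10): in a 180-sample cohort, 18 calls
(exactly 10%) is not problematic, 19 is. Flagged baits merge (gap 0) into
reported regions. The per-bait atom was chosen over per-merged-region
recurrence because all downstream accounting is in baits; a region-level
variant can be had by recomputing recurrence on merged calls.

Feature annotation: mappability is the length-weighted mean of a
bedGraph-style per-base uniqueness track over the bait (missing when no
base is covered, and logged); GC is (G+C)/(non-N length) from a FASTA via
pyfaidx, NaN for an all-N window; RPKM is reads × 10⁹ / (bait length ×
total mapped reads); the inter-sample CV is sd/mean with the n−1 standard
deviation (documented so the hand-computed oracle (1,3) → √2/2 pins the
estimator), missing — not zero — when the mean RPKM is 0; segmental-
duplication overlap keeps both the ≥ 1 bp flag and the covered fraction.

The comparison draws, per iteration, an equal-size sample without
replacement from the non-problematic baits and runs a two-sided Wilcoxon
rank-sum test per feature. The fixed variant is the normal approximation
with continuity correction and average ranks for ties
(`scipy.stats.mannwhitneyu`, asymptotic): group sizes here (tens to
hundreds) are far beyond exact-test regimes, and fixing the variant makes
the 1000-iteration summary reproducible. NaN feature values are excluded
within each test. All iterations derive from one seed through
`SeedSequence.spawn`, so results are byte-reproducible and independent of
iteration order.

## Filtration

Masking operates at the bait unit and removes flagged units from calls
*and* from the truth denominator — a caller's flagged baits are unreliable
for it in both directions, and keeping truth units there would charge the
caller false negatives at loci it was just forbidden to call. Each caller
is always filtered with its own mask (a union-mask mode exists for
consensus workflows). A whole-call removal mode (`apply_mask_to_calls`)
drops any CNV event overlapping the mask and leaves the truth denominator
alone, for users who filter call lists rather than re-benchmark; it is not
the default because per-caller truth denominators are what make pre/post
sensitivity comparable.

The pre/post test is a two-sided Wilcoxon signed-rank on per-sample count
differences with zero differences dropped (the standard convention); the
exact distribution is used up to 25 non-zero differences, the
continuity-corrected normal approximation above. Fewer than two non-zero
differences is reported as "not testable", never forced into a p-value.
Sensitivity gains are reported in percentage points, PPV changes as
post/pre fold-change (undefined when pre-PPV is 0).

## Synthetic-study generator

The generator emulates the *structure* of a clinical WES cohort with an
array-validated truth subset, not any particular caller's algorithm.
Defaults are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| cohort size | 180 samples | typical clinical WES batch with an array-positive subset |
| truth carriers / CNVs | 39 samples, 39 DEL + 59 DUP | array-confirmed truth subset of such a cohort |
| baits | 20,000 × 120 bp | enough for stable recurrence statistics at desk scale |
| toy genome | 8 × 5 Mb | keeps bait spacing (~2 kb) and the truth-exon fraction (~3,000/20,000) realistic; the tail 4% of each chromosome is bait-free so off-target decoys exist |
| truth CNV sizes | log-uniform 20–150 kb | must fit 5 Mb chromosomes and carry ≥ 10 SNP probes at array density |
| SNP-probe density | 1 / 2 kb, floor 1 | array-like support proportional to event size, giving the probe filter bite |
| artifact recurrence | 0.30 | well separated from the 0.10 threshold, so exact recovery is the expected outcome |
| artifact features | mappability −0.40, GC −0.10, depth-noise ×3, segdup co-location 0.8 | the documented signature of artifact-prone capture regions |
| caller profiles | sens 0.76/0.66/0.77/0.17, artifact baits 300/150/25/200, sporadic FP 8·10⁻⁴/10⁻³/6·10⁻⁴/4·10⁻⁴ per bait·sample | caricatures spanning sensitive-but-dirty, moderate, sporadic-noise-dominated and insensitive callers |

Clean truth CNVs are placed mutually disjoint (5 kb margin) so no
polymorphic locus arises by accident; filter "bite" comes instead from
explicit decoy array records — low-probe events, one locus shared by 6
samples, off-target events in the bait-free tails, and manually rejected
records. Decoys are array-side artifacts: emulated callers never see
them, which is what makes the noise-free configuration (no artifacts, no
sporadic FPs) yield PPV exactly 1.0. Artifact baits avoid truth baits so
planted-artifact recovery is unambiguous. Truth detection is per-exon
Bernoulli at the profile sensitivity, with only positionally consecutive
detected baits merged into one call segment — a segment never spans an
undetected bait, so realised per-exon sensitivity equals the parameter.
Depth counts are Poisson draws around bait-specific lognormal means with
per-sample scale factors; artifact baits get 3× the lognormal noise sigma,
which is what elevates their RPKM CV.

Everything derives from a single seed through named `SeedSequence`
substreams, so a fixed configuration is byte-reproducible and changing one
component's draw count does not cascade into the others.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: correlated errors between callers (real
callers share failure modes; simulated TP sets are conditionally
independent, so the simulated union sensitivity is optimistic), depth
perturbation by the true CNVs themselves, breakpoint uncertainty
(simulated calls are bait-aligned), reference-bias and batch effects in
depth, and real mappability/GC tracks (blocks are piecewise-constant).

## Numerical and degenerate-input conventions

Ties in rank tests use average ranks; classification, recurrence and
masking are pure set arithmetic with no tolerances. Degenerate inputs are
contracts, not accidents: empty call set → all-FN classification; empty
mask → identity filtration; mask covering everything → zero counts with
undefined metrics; all-zero depth row → missing CV excluded from
comparisons; empty flagged set → explicit "no problematic regions" error
rather than a vacuous comparison.

## Problem sizes used in the tests

Unit and property tests run on toy fixtures (tens of baits, ≤ 12 samples)
against brute-force oracles. The cohort-scale checks use the full default
conditions (180 × 20,000, four callers) — generation takes a few seconds —
and the feature comparison runs its full 1000 iterations. The acceptance
script repeats the cohort-scale analysis end to end from a user seed.

## Known limitations

The 10% recurrence threshold is a single global knob; cohorts with true
common CNVs (e.g. population CNPs overlapping the capture) will flag real
variation — the truth-side polymorphic filter mitigates but does not
remove this. Recurrence needs a reasonably large cohort: below ~50 samples
the binomial noise around the threshold makes recovery unreliable (the
tests demonstrate misses at n = 30). Masking at the bait unit cannot
express partial-bait artifacts, and event-level (breakpoint) accuracy is
out of scope entirely.
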