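# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical/design decisions taken where the
procedure was genuinely open.

## The counting model and the reliability framework

Expression here is digital: the number of non-redundant reads from a library
that best-match a gene, scaled to reads per million of that library's total
non-redundant reads. The denominator is deliberately the library's *full*
non-redundant read count, not the mapped-read count, so that a gene's value
is interpretable as a transcript rate within the library regardless of how
much of the library maps; a `denominator="mapped"` option exists for
sensitivity analysis.

At depths of 1.5–7 × 10⁴ reads per library, shot noise dominates low counts.
Treating counting as Poisson, an observed count N has relative statistical
error

    E[%] = 100 · k / √N,

where k selects the confidence level (1σ ≈ 68.3 %, 2σ ≈ 95.5 %,
3σ ≈ 99.7 %). The default working point E ≤ 25 % at k = 1 gives the count
cutoff N = ceil((100k/E)²) = 16; genes whose counts summed over the seven
early developmental stages fall below it are removed. The adult-intestine
library is excluded from this sum — reliability is judged on the
developmental time course only. The boundary is implemented as "sum ≥ 16"
with the comparison operator configurable, since either reading of the
boundary is defensible.

Two per-gene scores follow:

* **Depth stars** `τσ = floor(√(min_i N_i) / 4)` over the seven early-stage
  raw counts. The minimum is the default aggregator on the reasoning that a
  temporal dynamic is only as trustworthy as its least-sampled point; seven
  counts of 16 earn exactly one star, seven counts of 64 two stars. A
  mean-count aggregator is selectable (`aggregator="mean"`). This aggregation
  rule is the main free choice in the framework and is isolated in one
  function so alternatives can be swapped; candidate counts are sensitive to
  it, fold-change-based results are not.
* **Q-test stars** from the Dixon r₁₀ statistic on the seven *normalized
  expression* values (the quantities a reader of the profile actually
  compares; testing raw counts instead is available behind `q_on="counts"`).
  With sorted values x(1) ≤ … ≤ x(7), `q_low = (x2−x1)/(x7−x1)` and
  `q_high = (x7−x6)/(x7−x1)`; max(q_low, q_high) is compared to the n = 7
  critical values 0.507 / 0.568 / 0.680 (90 / 95 / 99 %, standard Dean–Dixon
  tables, config-overridable), worth 1 / 2 / 3 stars. A zero range makes the
  statistic undefined and scores no stars. No multiple-testing correction is
  applied across genes; the score is a per-gene flag, not a family-wise
  inference.

Genes with ≥ 2 total stars are candidates for clustering. The Q-test is
single-outlier by construction: a program elevated in *two* stages (e.g. a
postlarval program already partly expressed in the late competent veliger)
shrinks the gap statistic and can mask the outlier. This is a known property
of r₁₀, not a defect of the implementation, and it motivates keeping the
anticipatory pre-expression share moderate in the generator (below).

## Preprocessing

MID matching is 5′-anchored with a configurable mismatch budget, default 0
(exact). Ambiguous matches — more than one MID within budget — are discarded
to the unassigned pool rather than guessed, because cross-library
contamination would corrupt the per-library denominators. Cleaning trims a
leading adaptor, truncates at any interior adaptor occurrence (3′
read-through), 3′-trims at the first 10-base window whose mean quality drops
below Q20 (skipped when no qualities are present), and drops reads shorter
than 50 nt (strictly; a 50-mer survives). Duplicate removal collapses reads
with identical sequence (hence identical length) within a library, keeping
the first occurrence — order-stable and idempotent. A read that is a proper
substring of another is *not* a duplicate: at these read lengths independent
sonication fragments rarely coincide exactly, so exact identity is the
signature of amplification bias.

## Read-to-gene assignment

For real data the expected input is BLASTn tabular hits (outfmt 6); the
pipeline's own rules are only the E-value ceiling (hits with E ≥ 10⁻³⁰
discarded) and best-hit resolution: minimum E-value, ties broken by higher
score, then by lexicographically smaller contig id (a repository decision —
aligners do not document their tie order; it makes runs reproducible).

The bundled internal mapper exists so synthetic tests and self-contained
runs need no external aligner. It is deliberately minimal: exact 15-mer
seeds at non-overlapping offsets, ungapped verification over the full
overlap, a hit requiring identity ≥ 0.95 and overlap ≥ 50 nt, score =
matches − mismatches. Its surrogate E-value is `1e-35 · 2^(−score)`:
monotone decreasing in score (so best-hit resolution behaves identically)
and scaled to sit below the 10⁻³⁰ BLAST-domain ceiling for every hit the
mapper's own gates accept — the ceiling is calibrated to BLAST statistics
and would otherwise spuriously reject short perfect matches. The mapper is
substitution-only (no indels, no reverse strand), which matches the
generator's error model; it is not intended for real 454 data, where
homopolymer indels dominate.

## Clustering protocol

Exact zeros mean "below detection", not "absent", and a zero would pin the
row's median and break fold interpretation, so zeros become 0.0002 (the
scale of the fifth-smallest nonzero value in the motivating dataset;
configurable). Rows are then median-centered three times and scaled to unit
sum of squares five times — the repeated passes are part of the protocol
being reproduced; with a true median the first centering pass is already
exact, and rescaling preserves a zero median, so the final invariants (row
median 0, Σx² = 1, both within 10⁻⁹) hold regardless. "Each dataset" is read
row-wise (per gene): the stated sum-of-squares contract is a row contract.
A constant row becomes all-zero and cannot be normalized; it is dropped with
a logged warning.

Centroid linkage is implemented directly: the distance between clusters is
the metric distance between the arithmetic means of their members' processed
profiles. The default metric is Pearson correlation distance (1 − r), the
convention for expression profiles, with uncentered-correlation and
Euclidean options. scipy's centroid linkage is Euclidean-only and could not
express this rule, hence the in-package implementation; its oracle in the
test suite is an independent brute-force re-implementation. Determinism:
exact distance ties merge the pair whose clusters have the lexicographically
smallest (min-member-id, min-member-id) key; the initial distance matrix is
explicitly symmetrized because `corrcoef` is not bit-symmetric. Centroid
linkage can produce merge-height inversions; they are emitted as-is. Leaf
ordering visits the tighter-merging (lower-height) subtree first, ties by
smallest contained id. Outputs are the Cluster 3.0 CDT/GTR/ATR dialect
(GID/AID columns, unit GWEIGHT/EWEIGHT, similarities written as 1 − height)
readable by Java TreeView; `read_cdt` round-trips the ordered matrix
bit-exactly (values serialized with `repr`).

## qPCR concordance

qPCR series are fold-changes with the lowest stage set to 1. The
sequencing-side series is divided per stage by the geometric mean of the
internal control genes' expression — the standard combination rule for
reference-gene panels; the source protocol names two ICGs without stating a
rule, so single-ICG mode is also provided — then min-scaled to match the
qPCR convention. Pearson r is computed on the linear fold-change scale as
plotted (log scale behind a flag); since r is invariant under positive
affine maps, the scale matching is cosmetic and cannot change the class:
r > 0.75 strong, r > 0.6 acceptable, else weak; constant series are
incomparable (NaN). Flat genes correlate poorly under any noise — their
dynamics are noise-dominated — so concordance statements are meaningful for
genes with real fluctuation, and the test suite evaluates the Monte-Carlo
concordance bound on dynamic archetypes.

## The synthetic-data generator

The generator emulates the study design, not the sequencer. Defaults:

* **Depths** — the eight libraries' non-redundant read counts
  (38,923 / 33,423 / 41,160 / 30,296 / 22,441 / 14,853 / 67,916 / 58,026);
  column sums of the sampled count matrix equal them exactly (one
  multinomial draw per library).
* **Archetypes** — maternal decay (two-cell/morula fold uniform in 40–80,
  matching published per-gene drops of 78- and 57-fold), trochophore spike
  (spike/rest fold in 30–120; published examples exceed 100- and 30-fold),
  postlarval rise (fold in 25–60 over earlier stages; the motivating gene
  rises ≥ 29-fold), housekeeping (max/min ≤ 1.5 across the early stages),
  and low unstructured background. Default mix 8/8/8/16/60 %. Unconstrained
  stages carry lognormal jitter (σ = 0.15 on the log scale) — the true
  within-stage biological variance is unpublished, so this is a free
  parameter chosen to be visible but not archetype-breaking.
* **Normalization trick** — per-library normalization of abundances would
  distort cross-stage fold ratios, so background genes absorb per-library
  column-total differences before normalizing; configured folds of the
  structured archetypes are then *exact* in the normalized programs.
* **Anticipatory development** (`benthic_shift`, off by default) — the late
  competent veliger pre-expresses 0.3× of each rise gene's postlarval level,
  which makes the 74-h veliger and postlarva columns pair first in the stage
  tree while staying below the two-outlier masking threshold of the r₁₀
  statistic (at 0.6× the rise genes stop being detected as outliers at all —
  measured, and the reason the share is 0.3).
* **Reads** — each counted read is a uniform-random substring (50–600 nt,
  the gel size-selection window plus a short tail) of its transcript,
  decorated MID + adaptor + insert, with per-base substitution errors on the
  insert only. Distinct (start, length) pairs are drawn per gene and library
  so counted reads survive exact-duplicate removal, making the
  emit → preprocess → map → count round trip exactly identity on error-free
  runs. Duplicates are exact full-length copies appended with geometric tail
  probability d per copy, so the pool's duplicate fraction is d *and*
  post-dedup survival is 1 − d.
* **qPCR panels** — true stage abundances times lognormal noise, plus flat
  ICG rows (YB1/OAZ1).

Not emulated: 454 homopolymer/flowgram errors and indels, chimeras,
assembly input, isoforms, within-library biological replicates. Passing
tests therefore demonstrate the pipeline's bookkeeping, statistics and
determinism under the design's depth regime — not robustness to 454-specific
artifacts or to assembly error, which real runs must bring externally
(BLAST hits against a properly assembled reference).

## Problem sizes and determinism

The test suite and acceptance script run the count-level study at the full
per-library depths (300 genes) and the read-level round trip at 1/100 of
them (≈ 3,100 reads) — read emission is the only stage whose cost scales
with physical reads, and the round-trip checks are scale-free. Monte-Carlo
sizes: 2,000 flat genes for the Q-test false-positive bound, 1,000 random
instances (n ≤ 8) for the clustering oracle, 100 gene-seed pairs for qPCR
concordance. Every stochastic path takes an explicit seed and is
bit-reproducible; the acceptance script derives all of its seeds from
`--seed`.

## Known limitations

* The τσ aggregation rule (minimum vs mean) changes candidate counts; both
  are provided, neither can be validated without the original computation.
* Dixon r₁₀ detects exactly one outlying stage; two-stage programs are
  systematically under-starred (see above).
* Centroid linkage merge heights can invert; TreeView renders them, but
  height-threshold tree cutting is ill-defined across inversions (cutting by
  merge order, as `cut_tree` does, is well-defined).
* The internal mapper is for synthetic/verification use; real reads should
  come with BLAST tabular hits.
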