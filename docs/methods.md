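# Methods

This note documents the conventions, models and numerical choices behind
`sinreg`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinates, anchors and strand handling

All internal coordinates are 0-based half-open (the BED convention); GTF
input is shifted on read (`start := gtf_start − 1`). The TSS of a minus
strand gene is the last base of its interval (`end − 1`), the biological
5′ end; the TES is the opposite boundary. Oriented windows are expressed
as offsets in transcription direction with offset 0 at the anchor base;
for minus-strand genes the genomic interval is mirrored about the anchor
(`oriented_window` in `annotation_io`). This single rule generates every
strand-aware window in the package — the peak-assignment span, metagene
flanks, and the pausing windows — so flipping a gene's strand mirrors all
derived windows exactly, a property the test suite exercises directly.

Overlapping genes are allowed and a peak or base may belong to several
genes; no deduplication is attempted, and multi-assignment is visible in
the `n_peaks` column of target tables.

## Peak-to-gene assignment

A peak is assigned to a gene iff it overlaps, by at least one base, the
window from `upstream_bp` (default 1000) upstream of the TSS to
`past_tes_bp` (default 100) past the TES, oriented in transcription
direction. Overlap-by-1-bp is the simplest defensible criterion; a
summit-containment mode was considered and rejected as a default because
summits are absent from plain BED input. Windows are clipped at
chromosome start. Queries run on interval trees; correctness is checked
against an all-pairs brute-force oracle on random instances.

## Signal tracks and "enrichment"

`SignalTrack` stores sorted non-overlapping `(start, end, value)` runs per
chromosome with implicit zeros elsewhere; window queries materialize
per-base vectors via an interleaved run/gap expansion, so a window's
vector is exact rather than interpolated. The *enrichment value* of a
region is defined as the **mean** per-base signal (not the sum or max):
this makes the pausing ratio independent of window lengths and of gene
length. Whether a supplied track is raw coverage or input-normalized
enrichment is deliberately out of scope; the pausing index is computed on
whatever track is given, and that caveat travels with the results.

Out-of-bounds window bases (genes near chromosome ends, when sizes are
known) contribute zeros and are counted in a clipped-bases tally rather
than raising, so metagene matrices remain rectangular and deterministic
with an audit trail. Queries on absent chromosomes warn and return zeros.

## Metagene matrices

Reference-point (TSS-centred) mode only, ±3 kb with 10 bp bins by
default; flank must divide evenly into bins. Rows are oriented 5′→3′ so
column 0 is the most upstream bin in transcription direction. Within-bin
summary is the mean (median available as an option). Heatmap row order is
descending row mean with lexicographic gene-id tie-break — some fixed
order is required for deterministic output, and callers can pass their
own. Mass conservation (row sum × bin width = per-base window sum) is
property-tested to 1e-6 relative tolerance.

## Pausing index

Promoter window `[TSS − 50, TSS + 50)` and body window
`[TSS + 300, TES − 100)`, half-open in transcription orientation, matching
the package's global convention; the index is the ratio of the two window
means. Genes whose body window is empty or inverted (length ≤ 400 bp with
the default offsets) get status `excluded_short_gene`; genes with zero
body mean get `excluded_zero_body` rather than an infinite index, because
infinities poison rank statistics. Exclusions are counted and reported
alongside every group comparison. The index is invariant to positive
scaling of the whole track (property-tested), so between-sample scaling
does not affect within-track contrasts.

## Mann–Whitney U

Implemented from the rank-sum identity `U_a = R_a − n_a(n_a+1)/2` with
midranks for ties; the reported statistic is `min(U_a, U_b)`. The
two-sided p-value is exact — full enumeration of the
`C(n_a+n_b, n_a)` equally likely rank assignments, counting those with a
min-U at least as extreme — when the pooled sample has ≤ 12 values and no
ties; beyond that, a normal approximation with tie-corrected variance and
a 0.5 continuity correction is used. Zero tie-corrected variance (all
values identical) returns p = 1. The test is two-sided by default as the
conservative choice. Agreement with an independent reference
implementation is asserted to 1e-6 in the test suite; the implementation
itself never delegates to it.

## Regulation classification

|log2FC| bins: `< 2`, `[2, 3]`, `> 3`. The boundary values 2 and 3 fall
in the middle bin — the only reading consistent with "less than 2" and
"greater than 3" both being strict. Absolute values are used for both
directions. FPKM categories: `> 1000` strong, `[10, 1000]` moderate,
`[1, 10)` low, `< 1` silenced; placing exactly-10 and exactly-1000 in
"moderate" and treating the nominal 1–9.99 band as `[1, 10)` closes the
9.99–10 gap deterministically. The hard-candidate rule uses control FPKM
**≤ 1** (inclusive), deliberately distinct from the silenced category's
strict `< 1`; both rules are implemented verbatim rather than reconciled,
and each is applied only where its source analysis used it.

The TSS-localization score (mean profile within ±250 bp of the TSS over
the mean across the full window) is this package's own quantification of
a qualitative profile-shape contrast; reports flag it as such. It is 1.0
for a flat profile and grows with TSS concentration.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline is meant
to operate under: 500 genes with lengths uniform on 1–10 kb, 20% planted
repressed and 20% activated (100 genes per regulated group), half of all
genes bound, soft/mid/hard effect-size weights 0.9/0.06/0.04 with
|log2FC| uniform on (0.3, 1.8), (2.0, 3.0) and (3.2, 6.0) respectively,
planted promoter:body pausing ratios 5.0 (repressed) vs 1.5 (activated)
over Gamma(2, 1) body levels, and FPKM categories weighted
0.05/0.2/0.7/0.05 (silenced/low/moderate/strong) with log-normal
within-category values clipped into the category's range. True targets
receive p and FDR uniform below 0.04; unregulated genes uniform on
(0.05, 1). Hard-activated genes are forced to control FPKM ≤ 1, making
them detectable as switched-on candidates.

Design choices worth stating explicitly:

- **Stratified planting.** Discrete labels (direction, effect class,
  expression category) are apportioned by exact counts
  (largest-remainder) and shuffled, not drawn independently, so realized
  label proportions equal the configured weights up to rounding and
  recovery tests compare against sharp expectations. Continuous
  quantities are genuinely random.
- **Analytic pausing ground truth.** The signal is piecewise-constant —
  promoter at `r·b`, body at `b`, a per-base linear ramp between, constant
  0.1 background elsewhere — rather than read-level simulation, so the
  noise-free pausing index of every sufficiently long gene is exactly
  `r`. Poisson per-base resampling (optional) is applied within gene
  signal spans only; the background stays deterministic, which bounds
  track size while leaving the statistics the noise must exercise (the
  sampling variation of window means) fully intact.
- **Planted significance, not simulated DE calling.** p and FDR values
  are planted directly because upstream differential-expression calling
  is out of scope; only the output's statistical shape matters to the
  integration step.
- **Geometry guarantees identifiability.** Intergenic gaps are drawn
  from 1.8–2.6 kb, wide enough that a TSS-proximal peak (centre within
  ±200 bp of the TSS, width ≤ 600 bp) can never intrude into a
  neighbouring gene's assignment window, and decoy peaks are placed only
  in gaps with clearance from every window — so the bound/unbound ground
  truth is exact, not approximate.
- **Reproducibility.** All randomness flows from one
  `numpy.random.default_rng(seed)`; identical configs produce
  byte-identical on-disk datasets (asserted in the tests). Replicate
  studies derive child seeds by `SeedSequence.spawn`.

What the generator does *not* emulate: read-level noise and mappability,
fragment-size effects, input/IgG normalization, overlapping genes,
between-sample scaling, or any histone-mark structure. Passing recovery
tests therefore demonstrate that the *computations* are correct and
well-calibrated under the stated statistical structure — not that the
pipeline is robust to artifacts of real sequencing data.

## Calibration and power

`sinreg.calibration` runs the simulate → track → pausing → Mann–Whitney
pipeline over independently seeded replicates. Under the all-null
configuration (both groups at ratio 1.0, Poisson noise on, 120 genes per
group — a reduced gene count, since the false-positive rate of a rank
test does not depend on it) the fraction of p < 0.05 results across 200
replicates sits near the nominal 5%. Under the default planted contrast
(5.0 vs 1.5, 100 genes per group, noise on) the comparison detects the
difference at p < 0.01 in essentially every replicate. Both studies are
re-run from scratch by the acceptance script and asserted in the test
suite.

## Worked-example tables

The original isoform study reports its integration results as summary
counts. `sinreg.worked_examples` expands such counts into explicit
tables — synthetic gene identifiers, representative in-bin values — so
the same summary operations that serve the pipeline re-derive each
reported percentage from raw counts. Only the counts are real; the
per-gene rows are labelled stand-ins for unpublished gene lists.

## Known limitations

- One interval per gene: transcript isoforms with alternative TSSs are
  not modelled; if a gene has several annotated starts the caller must
  choose one interval per gene id.
- bedGraph ingestion rejects overlapping input intervals rather than
  resolving them; tracks must be pre-flattened.
- The pausing comparison assumes the two gene groups are disjoint and
  refuses otherwise (a test-only escape hatch exists for the
  self-comparison sanity check).
- Percentages are reported both to one decimal and integer-rounded;
  consumers comparing to externally printed integers should use the
  integer form.
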