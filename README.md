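# sinreg

Downstream analysis of SIN3-isoform gene regulation in *Drosophila* S2
cells: integration of ChIP-seq binding with RNA-seq differential
expression into direct-target gene sets, TSS-anchored metagene signal
profiling, an RNA Pol II promoter-proximal pausing index with
nonparametric group comparison, and soft/hard regulation classification —
plus a fully labelled synthetic-data generator so that every stage of the
pipeline is verifiable end to end without downloading any sequencing data.

The package is aimed at regulatory genomicists who have peak calls
(BED/narrowPeak), signal tracks (bedGraph), gene annotations (GTF/BED6)
and differential-expression/FPKM tables, and want reproducible,
unit-tested versions of the standard integration steps rather than a
chain of one-off scripts.

## The computations

**Direct targets.** A peak is assigned to a gene when it overlaps (by at
least 1 bp) the strand-aware window from 1 kb upstream of the TSS to
100 bp past the TES. A gene is a *direct target* if it is bound and
significantly differentially expressed when the factor is perturbed
(defaults FDR < 0.05, p < 0.05). Direction depends on perturbation
polarity: under knockdown, log2FC > 0 ⇒ repressed by the factor; under
overexpression the mapping inverts.

**Metagene matrices.** For a gene set, per-base signal over
[TSS − 3 kb, TSS + 3 kb) in transcription orientation is averaged in
10 bp bins into a genes × bins matrix; column means give the average
binding profile.

**Pausing index.** Per gene,

&nbsp;&nbsp;&nbsp;&nbsp;PI = mean signal over [TSS − 50, TSS + 50) ÷ mean signal over [TSS + 300, TES − 100)

in transcription orientation. Genes shorter than 400 bp or with zero body
signal are excluded and tallied. Group contrasts (repressed vs activated
targets) use the two-sided Mann–Whitney U test — exact by full enumeration
for small tie-free samples, tie-corrected normal approximation with
continuity correction otherwise.

**Regulation classes.** Direct targets are binned by |log2FC| (soft < 2,
mid 2–3, hard > 3; a log2FC of 2 is a 4-fold change) and by control-cell
expression (FPKM > 1000 strong, 10–1000 moderate, 1–9.99 low, < 1
silenced). *Hard-regulation candidates* are activated targets with
control FPKM ≤ 1 — genes apparently switched on from silence rather than
fine-tuned — and their TSS binding localization is contrasted against all
activated targets.

**Synthetic data.** `sinreg.synthetic_data` simulates a labelled
chromosome: non-overlapping genes, TSS-proximal peaks for a planted bound
set, a piecewise-constant polymerase-like track with planted promoter:body
ratios (5.0 for repressed, 1.5 for activated genes by default, optional
Poisson noise), and DE/FPKM tables with planted soft/mid/hard effect
mixtures and expression categories. Every planted label is recoverable by
the corresponding pipeline stage, which is what the test suite checks.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on the
synthetic dataset (`python analysis/01_simulate_dataset.py` through
`06_reported_counts.py`), writing tables under `results/`. Highlights of
an actual run:

```
$ python analysis/02_direct_targets.py
200 direct targets called ({'activated': 100, 'repressed': 100});
recovered 200/200 planted targets, 0 spurious

$ python analysis/04_pausing_index.py
median pausing index: repressed 5.00 vs activated 1.50
Mann-Whitney U = 0, two-sided p = 1.45e-34 (normal_tie_corrected)

$ python analysis/05_regulation_classes.py
|log2FC| bins (repressed): {'lt2': 90.0, 'two_to_three': 6.0, 'gt3': 4.0}
hard candidates: 9 of 100 activated targets (9/9 planted recovered)
TSS localization score: candidates 1.39 vs all activated 1.26
```

All 200 planted direct targets (100 repressed, 100 activated) are
recovered with no false calls; the pausing medians equal the planted
promoter:body ratios exactly (noise off); the |log2FC| bin percentages
match the planted 90/6/4 soft/mid/hard mixture; and all planted
activated-but-silent candidates are detected. The TSS localization score
is the mean profile within ±250 bp of the TSS over the mean across the
full ±3 kb window (1.0 = flat, larger = more TSS-peaked).

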