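# Methods

This note documents the model and procedure implemented by `nccm`, the
choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## The burden model

The unit of analysis is the per-gene **noncoding target region**:
`clip([tx_start − flank, tx_end + flank), chromosome) \ ⋃ CDS(all genes)`,
with all coordinates 0-based half-open. Three choices fix its
semantics:

* **CDS exclusion is global.** A flank that reaches into a neighbouring
  gene must not pick up that gene's coding bases, so the union of CDS
  over *all* genes is subtracted, not only the focal gene's. This is
  the conservative reading of "excluding protein-coding sequence".
* **Flanks are symmetric and strand-ignored**, anchored at the
  transcribed span (default 100,000 bp per side). Strand is read and
  stored but does not change geometry.
* **Shared loci multi-assign.** A variant inside two genes' target
  regions counts once toward each gene. Reports group genes sharing at
  least one NCCM into loci (connected components), so the sharing is
  visible, but counts are never deduplicated — a burden rate is a
  statement about one gene's neighbourhood, not a partition of
  mutations.

A variant's functional class is decided per base: *coding* if any
affected reference base overlaps any CDS (for a deletion, any deleted
base; an insertion sits at its anchor base), else *noncoding_target*
with the list of genes whose target contains the first affected base,
else *noncoding_other*. Exactly one class per variant.

## Constraint cutoff

Scores are phyloP-like, clipped to [−20, +9]; unscored positions are
NaN and are never treated as 0. Two cutoff modes:

* `fixed` (default 1.2) reproduces the published parameterisation in
  which 1.2 is the empirical top-8% threshold of the 240-mammal track;
* `percentile` computes, over *scored* positions only, the smallest
  score *c* with `frac(score ≥ c) ≤ f` (default f = 0.08). The
  inclusive ≥ rule means ties can only push the realised fraction
  *below* f — calls stay conservative; in the fully tied degenerate
  case nothing passes.

Indel scoring is the pipeline's own policy (the upstream convention is
unstated): by default the maximum score over the affected span
(deleted bases; the two bases flanking an insertion point), with a
`first_base` alternative available and reported. Both the NCCM score
condition (`score ≥ c`) and both candidate thresholds
(`rate ≥ 2/100 kbp`, `count ≥ 5`) are inclusive.

## Cohort statistics

* **Cohort comparison** uses Welch's unequal-variance *t* on
  per-patient rates (all genes, and each cohort's own top 0.5% by
  rate). Welch is chosen over the pooled-variance form because the two
  cohorts' rate distributions differ strongly in scale; the choice is
  reported in the output.
* **Confounders**: Pearson *r* of NCCM count vs gene span, and of NCCM
  rate vs local mutation rate and GC content. "Local mutation rate" is
  defined here as *all* somatic mutations (any class) in the gene's
  target window per bp. Repeat-region overlap of top-gene NCCMs is
  compared with the repeat genome fraction by a two-sided binomial
  test — a formalisation this pipeline adds to the qualitative
  "less often than expected" check.
* **Signature shift**: signatures pass a two-gate inclusion filter
  (≥ 5% of mutations in at least one sample AND present in ≥ 10% of
  samples, both inclusive), then a 2×2 Fisher exact test on pooled
  per-class counts (coding vs NCCM with/without the signature). The
  two-sided p uses the point-probability rule (sum of table
  probabilities ≤ the observed table's); a doubled one-sided rule is
  available by flag. Pooling across samples matches the astronomically
  small p-values such shifts produce at cohort scale. The odds ratio
  reported is the conditional MLE.
* **Stratified rates** recompute the burden per stratum (subgroups;
  pediatric < 18 y / adult ≥ 18 y, age 18.0 exactly is adult) with the
  stratum's own sample count as denominator. Samples without a
  subgroup label join age strata only. Pairwise stratum similarity
  uses Kendall τ-b — tie-corrected, because candidate-gene rate
  vectors are mostly zeros; strata below a minimum sample count
  (default 5, e.g. a 3-patient WNT stratum) are excluded from the
  default matrix. For the pediatric/adult pair both τ-b and Pearson
  *r* are emitted, since either convention is defensible for that
  scatter.

## Synthetic cohort generator

The generator is the package's study stand-in, not a fixture: gene
models are packed with small exons and dominant introns (exon/intron
slack weighted 1:30, mirroring real gene anatomy), every multi-exon
gene has UTR on both sides, and each default chromosome contains at
least one gene pair within 100 kbp to exercise shared-locus
assignment. The constraint track is a two-component Gaussian mixture —
background N(0,1), constrained N(3,0.5) at 8% of positions, clipped to
[−20, 9] — whose analytic 92nd percentile (~2.37) is the reference
point for calibration tests. Default cohorts mirror the study design:
an MB-like cohort of 146 samples at ~1,400 mutations/sample
(negative-binomial, dispersion 2) with subgroup proportions
3 WNT : 37 SHH : 43 group 3 : 60 group 4 : 3 unclassified and a
bimodal age model in which SHH carries the adult mode, and a PA-like
cohort of 89 samples at ~300 mutations/sample.

Background mutations are placed uniformly over the genome — the study
treats regional rate variation as a confounder to test for, and a
uniform null keeps every expectation analytic (a per-chromosome rate
multiplier exists for confounder experiments). Planted drivers draw
`Poisson(rate × target_len / 10^5)` extra mutations at
constraint-passing positions of their own target region, assigned
round-robin across the configured stratum's samples (an option
concentrates two per patient). Signature labels are drawn directly
from class-dependent profiles — no trinucleotide modelling — because
only per-class proportions feed the shift test; the default profiles
put the clock-like SBS1 at 45% of coding vs 12% of NCCM mutations,
the direction the analysis is meant to detect.

**What passing tests do not show.** The generator's genome is i.i.d.
sequence with single-base constrained positions scattered at random;
real constraint comes in multi-base elements, real mutation rates vary
with replication timing and chromatin, and real annotation tracks are
enriched at constrained *elements* rather than isolated bases (which
is why the synthetic regulatory-overlap fractions sit near track
coverage instead of the >45% seen on real data). Recovery of planted
drivers therefore demonstrates the statistical machinery, not
performance on real tumour genomes.

## Problem sizes and numerics

Test and acceptance runs are scaled to desk size as the package's own
choice of study conditions: the driver-recovery experiment uses 2,000
mutually isolated genes (50 kb spans, ≥220 kb inter-gene gaps so
±100 kb targets never overlap, ~248 kb target each) on a 2×271 Mb
genome, one genome shared across 10 cohort seeds; near-Poisson count
dispersion (50) keeps the realised background at its nominal
0.3 NCCMs/100 kbp, under which the analytic per-driver pass
probability at the 2/100 kbp threshold is ≈ 0.91 and the expected
background false positives ≈ 1.5 per seed. Percentile calibration is
exercised at 10^6 positions, where the mixture's empirical quantile is
within 0.05 of the analytic value and the realised constrained
fraction within ±0.005 of 8%.

Numerical conventions: dense float32 tracks (bedGraph written at %.9g,
which round-trips float32 exactly); cutoff tie-breaks as above, in the
track's own dtype; candidate sets sorted by descending rate then gene
id so ties are deterministic; all randomness flows from one seed
through named substreams, making full pipeline runs byte-identical.
TSV floats are written at %.6g, summaries as strict JSON (NaN → null).

## Known limitations

Transcript-isoform-aware annotation, promoter/splice-site categories,
signature extraction from trinucleotide spectra, and significance
testing of burden against a background mutation model are all out of
scope — candidates are defined by fixed thresholds, exactly as in the
source procedure. GFF3 support covers the gene/mRNA/exon/CDS subset;
bigWig tracks are not read (bedGraph/wiggle are the reference
dialects). Whether the published candidate set applied the rate
threshold to cohort-aggregate or per-patient-scaled rates is ambiguous
in the source; this implementation applies it to the cohort-aggregate
rate and reports the per-patient rate alongside in every table.
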