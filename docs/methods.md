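# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `panlandscape`. Every
threshold mentioned here is a named configuration key
(`panlandscape.pipeline.Thresholds`), never a literal buried in the code.

## Inputs and sample matching

All layers travel as dense genes × samples TSV matrices with declared
semantics (`raw_count`, `normalized_expression`, `beta`, `cnv_call`,
`protein_level`, `drug_auc`); validation is enforced on read (betas in
[0, 1], calls in {−2…+2}, counts non-negative integers). Missing values
are written as `NA` and handled pairwise-complete in correlations.
Somatic mutations use the standard tab-separated MAF with the five columns
`Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification,
Reference_Allele, Tumor_Seq_Allele2`, plus an explicit cohort sample
universe so unmutated samples count in frequency denominators.

Samples are identified by TCGA-style barcodes. The parser accepts any
barcode with ≥4 dash fields and reads the first two characters of the
fourth field as the sample-type code: 01–09 tumor-derived, 10–19
normal-derived (01 = primary tumor and 11 = solid tissue normal are what
the generator emits). Tumor/normal splitting and cross-layer matching use
this code and the participant fields; matching is the symmetric
intersection of sample sets.

## Stage statistics

**Differential expression.** Counts are normalized with median-of-ratios
size factors (reference set: genes with positive counts in all samples;
factors rescaled to geometric mean 1). The effect size is
`log2((mean normalized tumor + 0.5) / (mean normalized normal + 0.5))`;
the p-value is a Welch two-sample t on `log2(normalized + 1)`. Within each
cancer, p-values are Benjamini–Hochberg adjusted across the tested genes.
A gene is `up` (`down`) when log2FC ≥ 1 (≤ −1) — i.e. at least a two-fold
change, boundary inclusive — and FDR < 0.05. The pseudocounts (0.5 in the
fold change, 1 in the log transform) are fixed so tests can assert exact
values. This deliberately simple, fully specified statistic replaces a
shrinkage-based DE engine; the landscape, not the DE machinery, is the
subject of the package.

**CNV landscape.** Gene-level thresholded calls use the conventional
five-level coding (−2 homozygous deletion … +2 homozygous amplification;
heterozygous = one chromosome copy affected, homozygous = both).
Percentages are per category over non-missing calls; a gene is *displayed*
when the union of the four event percentages strictly exceeds 5% (exactly
5.0% is excluded). A `per_category` flag applies the rule to each category
instead, since either reading of the display convention is defensible.
CNV–expression association is Spearman on the integer call (average ranks
for ties, p from the t-approximation), BH-adjusted per cancer.

**Methylation.** Input is one beta value per gene per sample (promoter
probes collapsed upstream, e.g. by their mean; the pipeline consumes the
collapsed matrix). Tumor–normal differences use Student's pooled-variance
t on the betas — pooled, not Welch, is the convention followed here —
with BH per cancer; `hyper`/`hypo` requires FDR < 0.05. The
methylation–expression correlation is Spearman on barcode-matched samples
only; genes with <3 matched pairs yield missing-result rows rather than
errors.

**Mutations.** A sample is mutated for a gene iff it has ≥1 non-silent
record for it, counted once regardless of variant multiplicity; Silent
records are excluded from frequencies (`include_silent` flips this) but
retained in the class spectra under their own label. The frequency
denominator is the full cohort universe. SNV base changes collapse to the
six pyrimidine-context classes (G>C → C>G etc.); indels and multi-base
changes are non-SNV. No driver-significance testing or mutual-exclusivity
analysis is attempted.

**Pathway activity.** RPPA components are centered on their median and
scaled by the standard deviation across patients (n−1 convention;
zero-variance components dropped with a warning; the transform is
idempotent on its own output). The pathway activity score of a sample is
the sign-weighted *mean* of member levels — mean rather than sum so scores
are comparable across pathways of different sizes, with inhibitory members
entering negatively. For each (gene, pathway, cancer): samples split at
the gene's median expression (strictly-greater goes high; ties go low,
fixing behavior at even/odd n), Student's t on PAS between halves, BH per
cancer across all gene × pathway cells. `pas_global_summary` reports the
percentage of cancers activated/inhibited and keeps a pair for the heatmap
when it is functional in ≥5 cancer types (boundary inclusive). The ten
default pathway definitions (apoptosis, cell cycle, DNA damage response,
EMT, hormone AR, hormone ER, PI3K/AKT, RAS/MAPK, RTK, TSC/mTOR) carry
synthetic member components — real antibody panels are configuration, not
shipped data.

**Drug response.** Spearman correlation between gene expression and drug
AUC across shared cell lines is the headline statistic (a Pearson variant
is available via `method="pearson"`). Each rho is Fisher-Z transformed
(z = atanh(rho), rho clipped to ±(1−10⁻¹²)). Significance is a two-tailed
test at family-wise alpha 0.05 — 0.025 per tail — Bonferroni-corrected
over all gene × drug pairs. Positive rho (higher expression, higher AUC)
is annotated `resistance`, negative `sensitivity`. The resampling
comparison takes a target pair set, computes its mean |rho| (absolute
value, since both directions count as drug-related), and compares it to
the same statistic on equally sized random draws (without replacement)
from the non-target pairs; `empirical_p = (1 + #{null ≥ observed}) /
(1 + iterations)`.

**Survival.** Expression is median-split (ties low) and the two groups
compared with the standard two-group log-rank test: hypergeometric
expected deaths accumulated over distinct event times, chi-square with
1 df. The verdict at p < 0.05 is `unfavorable` when the high-expression
group has more observed than expected deaths, `favorable` otherwise. The
median-split + log-rank design was chosen over a Cox model because it
needs no iterative fitting and yields exactly the binary
favorable/unfavorable presentation the landscape reports; the O−E sign
plays the role of a hazard-ratio sign. Per-gene calls are unadjusted by
default (one prognostic call per gene); `adjust_fdr=True` applies BH.

## Synthetic cohort model

One latent expression value per sample links the layers, so cross-layer
correlations in the generated data are real rather than coincidental.
Per cancer type and gene:

- Baselines: mean expression log-uniform on [2⁴, 2¹²]; baseline promoter
  beta uniform on [0.15, 0.85].
- Counts: negative binomial via gamma–Poisson with a single global
  dispersion (default 0.1, the simplest model that makes the DE test
  non-trivial). The tumor mean is multiplied by 2^planted-log2FC.
- CNV: calls drawn i.i.d. from configurable event rates (default
  0.05/0.15/0.60/0.15/0.05 for −2…+2 — a frequently altered locus, so the
  correlation stage has events to work with); the expression mean is
  multiplied by (1 + slope·call/2), clipped away from zero.
- Methylation: beta = logistic(mu + Δ·tumor + noise), logit-scale noise sd
  0.5; Δ is chosen so the planted tumor−normal *beta* shift is attained at
  the gene's baseline. Expression is co-perturbed by
  slope · (logit-beta residual), which plants the negative
  methylation–expression correlation without double-counting the planted
  group means.
- Mutations: a non-silent record per (tumor, gene) with the planted
  probability (class mix Missense:Nonsense:Frame_Shift_Del = 7:1:1), plus
  an independent Silent record at a tenth of that rate — approximately the
  70/10/10/10 spectrum while keeping the silent-excluding frequency
  estimator unbiased for the planted value. Half of SNVs are forced into
  the C>G class (configurable enrichment).
- RPPA: member levels N(0, 1); each planted (gene, pathway, cancer) adds
  sign·shift to the pathway's members for the gene's expression-high half,
  so the realized PAS displacement equals the planted value.
- Drug AUC: Gaussian copula — AUC latent = rho·z_gene + √(1−rho²)·noise
  per planted pair; at most one planted gene per drug.
- Survival: exponential event times; each planted gene multiplies the
  hazard of its expression-high half by 2 (`unfavorable`) or 0.5
  (`favorable`); independent exponential censoring tuned to ≈30% censored.

The same config + seed reproduces every file byte-for-byte; all draws come
from one `numpy.random.default_rng(seed)` consumed in a fixed order.

Default planted effects are the study conditions the landscape is meant to
surface: HIF3A/EPAS1 two-fold down and HIF1A/ARNT ±1.5-fold; dosage slope
0.5 for all six genes; ±0.2 beta shifts with slope −0.8 on the logit
scale; mutation frequencies 17–26% (31% for EPAS1 in UCEC); EMT activation
(+1) for all six genes plus PI3K/AKT for HIF3A and cell-cycle/DNA-damage
inhibition (−1); EPAS1 correlated with five drugs (docetaxel strongest at
−0.6); HIF1A/ARNT/EPAS1/HIF3A unfavorable and ARNTL/ARNT2 favorable
survival directions.

## What the generator does and does not emulate

It reproduces the *statistical shapes* the pipeline consumes — overdispersed
counts, bounded betas, five-level calls, MAF records, protein z-scores,
AUC latents, censored times — and verifiable cross-layer couplings. It
does **not** attempt real TCGA effect-size distributions, cohort sizes,
gene–gene correlation structure, batch effects, probe-level methylation,
or real antibody panels. Passing recovery tests therefore demonstrates
that the statistics detect what they claim to detect at the stated sizes
and stay calibrated under the null — not that the pipeline's calls on real
portal data would match any particular published figure.

Two power properties of the defaults are worth knowing. First, at the
default 40 tumors per cancer the per-cancer log-rank and PAS tests are
deliberately under-powered (sensitivities well below 1 in the recovery
scores); the acceptance tests use the sample sizes each statistic needs
(200 for survival, 300 cell lines for drugs). Second, when several genes
plant shifts on the *same* pathway's members (as the default EMT condition
does), the overlapping shifts inflate member variance, and the per-patient
SD normalization then shrinks every gene's marginal displacement — a real
interaction, not a bug, which is why the default cohort's PAS sensitivity
is modest while a single-gene planting is recovered ≥90% of the time.

## Numerical choices and degenerate inputs

- BH is computed on the finite entries only; NaN p-values (degenerate
  correlations) pass through as NaN and do not count as tests.
- t-tests on zero-variance data: equal means give p = 1, unequal means
  p = 0 (rather than NaN).
- Spearman needs ≥3 complete pairs and non-constant inputs; otherwise the
  record is a missing-result row, never an exception, so one degenerate
  gene cannot abort a landscape run.
- Spearman p-values use the t-approximation
  t = rho·√((n−2)/(1−rho²)) throughout, including the vectorized
  rank-then-Pearson batch path, which matches the scalar path to 1e-12.
- Matrix and report TSVs round-trip exactly: floats are written at full
  repr precision and parsed back with round-trip parsing.
- Median splits send ties to the low group everywhere (PAS and survival),
  so even-n behavior is deterministic.

## Problem sizes used by the shipped checks

The test suite's recovery experiments use 100 seeded replicates per stage
at the sizes named above; null calibration uses one 500-background-gene
cohort per stage, 100 replicates of a 100 × 50 null drug screen for the
family-wise error, and 200 null resampling runs. The acceptance script
runs the full default cohort (11 cancers × 60 samples, 206 genes, 120 cell
lines × 30 drugs) in a few seconds on one CPU. These sizes were chosen to
make the statistical assertions decisive while keeping any single check in
the seconds-to-minutes range.
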