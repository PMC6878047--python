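# Methods

`wingqtl` implements a multi-layer association workflow for organ-size
variation on a panel of fully inbred *Drosophila* lines: RNA-seq
preprocessing, three-type trait–expression association, permutation-corrected
cis-eQTL mapping, triangular mediator selection, and an additive unit-sign
eQTL score that predicts line-level wing size. Because the workflow is meant
to be testable without any external downloads, the package ships a
first-class synthetic cohort generator whose planted ground truth drives all
statistical tests. This note records the models, the defaults and why, the
numerical choices, and what the synthetic results do and do not establish.

## The measurement model

Wing size is summarised per line and sex by the absolute centroid size
(absCS) of the wing and by a body-size-adjusted version (relCS). The
adjustment convention is: within each sex, regress absCS on the interocular
distance (IOD) and keep the residual, shifted back by the per-sex mean absCS.
This preserves centroid-size units and the female–male offset while removing
the allometric body-size component. The convention is a package choice (the
adjustment is usually inherited from morphometric pipelines that do not state
a formula) and is flagged in the cohort manifest.

Genotypes are homozygous: each line carries 0 (reference) or 1 (alternate)
at a biallelic site, with missing calls kept as a distinct status and never
imputed. All regressions on genotype use this 0/1 coding; a diploid 0/1/2
coding would be degenerate on an inbred panel.

## Expression preprocessing

Raw counts (genes × samples) pass through, in order:

1. **Sample filter.** Samples with library size below `min_library_frac`
   (default 0.25) times the median library are dropped. The default is
   conservative and logged; it exists to remove failed libraries, not to
   trim the depth distribution.
2. **Gene filter.** A gene is kept iff its total count across retained
   samples is at least 70% of the number of samples. Below that depth a
   count-based signal cannot be distinguished from sampling noise.
3. **log-CPM.** `log2((count + 0.5) / (library + 1) * 1e6)`.
4. **Precision weights.** Count data are heteroscedastic on the log scale,
   so each observation receives an inverse-variance weight from a fitted
   mean–variance trend: expression is regressed on the line×sex design,
   each gene contributes (mean log2 count, sqrt(residual SD)) to a lowess
   smoother (frac 0.5), and the weight is the interpolated trend value at
   the observation's fitted log2 count raised to the −4th power, clipped to
   [1e-3, 1e3]. A unit-weight mode exists for ablation.
5. **Batch-PC removal.** The first `k = 2` sample-space principal
   components, computed on gene-standardised expression (standardisation
   stops a few high-variance genes from steering the directions), are
   regressed out of every gene with the gene mean restored. The residuals
   are exactly orthogonal to the removed scores. `k` is configurable;
   removal happens at the sample level, before replicate averaging.
6. **Summarisation.** Replicates are averaged per line×sex; weights add,
   as inverse variances of a mean of independent observations do.

Steps 3–5 never change matrix dimensions; filters run samples-first and are
idempotent on already-filtered input.

## Trait–expression association

Three weighted-least-squares models are fitted per gene on line×sex values
(weights from step 6 when present):

* **type 1** `expr ~ absCS` pooling sexes — overall size association,
  including the dimorphism axis;
* **type 2** `expr ~ sex + trait` (trait ∈ {absCS, relCS}) — a
  parallel-slopes ANCOVA isolating between-line association within sexes
  (no sex×size interaction by default);
* **type 3** `expr ~ sex` — sexually dimorphic expression.

The reported p-value is the t-test on the size term (types 1, 2) or the sex
term (type 3). Benjamini–Hochberg adjustment is applied within each
(layer, model, trait) family separately, matching how per-analysis
thresholds are quoted; genes flagged untestable (fewer than 4 units,
constant regressor, or no residual degrees of freedom) are excluded from the
family size so they do not deflate the adjusted values. Classification at an
FDR threshold (default 20%): a gene significant for type 1 but neither
type-2 family is *type-1 exclusive*; if its type-3 test is also significant
it is a *confirmed type-3* gene — dimorphic expression tracking the
between-sex rather than the between-line size axis.

## cis-eQTL mapping

Variants are filtered to minor allele frequency ≥ 10% (computed over
non-missing lines, boundary kept). A variant is cis to a gene iff it lies on
the same chromosome within ±100 kb of the gene body (inclusive); everything
else is trans. Per sex, each gene's line-level expression is regressed on
the alt indicator of each cis variant; lines with a missing call drop out of
that pair, and pairs monomorphic after missing removal are skipped and
counted.

Multiple testing across a gene's variants uses the permutation min-p
scheme: for each of `n_perm` rounds, one shared permutation of line labels
is applied to the whole expression matrix (one shuffle per round preserves
gene–gene correlation), the scan is repeated, and the minimum nominal p per
gene is recorded. The corrected p is the fraction of permutation minima
strictly smaller than the observed minimum — exactly that ratio, so it can
be zero; a positively biased `(k+1)/(n+1)` count is available behind a
flag. Family-level control uses the empirical FDR
`FDR(t) = t·G / #{corrected_p ≤ t}`; the reported threshold is the largest
grid value with FDR at or below the target. Variant-level calls for a
significant gene use the gene's own permutation quantile: with threshold
`t`, the nominal cutoff is the `(⌊t·n_perm⌋+1)`-th smallest permutation
minimum, and every tested variant at or below it is reported. The default
of 10,000 permutations matches the workflow's original setting; the test
suite and the acceptance script use 200, which bounds the corrected-p
resolution at 0.005 and is sufficient for a 20% FDR decision at a few
hundred genes.

Density profiles around transcript anchors are strand-aware: distances are
measured in the direction of transcription (upstream negative) from the TSS
and TES, binned (default 5 kb) within ±100 kb, and normalised per kb.

## Mediator triangulation and the flow model

A mediator gene must satisfy three links for a given (sex, trait)
condition: a type-2 association at 20% BH FDR, a gene-level eQTL at 20%
empirical FDR, and at least one linked eQTL variant itself associated with
the trait (per-variant regression, nominal p < 0.05; R² reported).
Mediator sets are kept separate per condition because the relevant genes
and variants differ between sexes and traits.

Each surviving (variant, gene) pair becomes one unit-strength entry:
`net_sign = sign(eQTL beta) × sign(type-2 slope)` — the predicted push of
the alternate allele on wing size. A line's net score is the sum of net
signs over entries where it carries the alternate allele; reference alleles
contribute zero and missing calls contribute zero but are counted. All
linked eQTLs enter the sum (entries are eQTLs, not genes). The score is
integer-valued and bounded by the number of assigned entries.

In-sample agreement is reported as the Spearman correlation between raw net
scores and the observed trait. For out-of-sample prediction, a univariate
least-squares calibration `trait ~ net_score` is fitted on the training
lines only and applied to disjoint holdout lines; 50% and 95% prediction
bands come from the residual t distribution.

## The synthetic cohort generator

One master seed drives everything; submodule seeds are derived by labelled
hashing, so cohorts are bitwise reproducible and stages can be regenerated
independently.

* **Genome.** Non-overlapping gene models placed in per-chromosome slots
  (1–10 kb, random strand); variant positions uniform. Defaults: 300
  genes, 3,000 variants on three chromosomes.
* **Genotypes.** Blockwise copy-with-flip haplotypes: within a 20 kb block
  the first variant is Bernoulli at an alt frequency drawn from
  [0.1, 0.5] and later variants copy it, each line reverting to an
  independent draw with probability 0.1 (`ld_corr = 0.9`), reproducing the
  tight local linkage seen among cis variants on real inbred panels.
  1% of calls are set missing.
* **Phenotypes.** `absCS = 160 + 15·[female] + Σ mediator SNP effects +
  line effect (SD 2) + noise (SD 0.5)`; IOD is generated with partial
  correlation 0.5 to the line component, and relCS follows the residual
  convention above. The +15 female offset against a between-line SD of 2
  mirrors a strongly dimorphic trait whose within-sex variation is an
  order of magnitude smaller.
* **Counts.** Negative binomial with shared per-gene dispersion 0.05 and
  log2-link latent means: baseline Uniform(3, 9), planted sex effects
  (types 1, 3; 1 log2 unit), planted within-sex slopes (types 1, 2;
  0.15 log2 per absCS unit), planted cis-eQTL effects (1 log2 unit, placed
  near the TSS/TES with probability 0.8), per-line biological noise
  (0.2 log2), and a rank-two technical structure. The technical part is
  deliberate: replicates alternate between two library preparations and
  lines split into two processing cohorts, each factor with independent
  per-gene loadings (SD 0.8 log2). This emulates a study whose two leading
  expression PCs are technical — which is precisely the regime in which
  regressing out the first two PCs is the right conditioner. With a
  rank-one batch, the second PC would be the strongest biological axis and
  the fixed 2-PC removal would erase planted signal; the generator
  therefore encodes the assumption under which that preprocessing step is
  valid.
* **Mediators.** 8 of the 20 type-2 genes also receive a cis-eQTL and a
  phenotype effect of 2 absCS units (one between-line SD per entry), with
  the SNP→trait sign matched to sign(eQTL beta)×sign(slope) so the planted
  triangle is causally coherent. Holdout panels reuse the same variants and
  truth with freshly drawn lines.

**What the generator does not emulate:** read-level artefacts (UMIs,
barcodes, mapping bias), population structure and long-range LD,
GC/length-dependent count bias, trans-regulatory networks, and
expression–phenotype confounding beyond the planted links. Passing tests
therefore demonstrate that the estimators are correct and calibrated under
the stated generative model, not that the biological conclusions of any
particular study are right; real-data behaviour additionally depends on the
artefacts listed above.

## Numerical choices and degenerate inputs

Weighted fits use batched normal equations per gene (the designs are
3-column at most; conditioning is not a concern at these sizes). Exact fits
report p = 0 rather than NaN. Spearman statistics use average ranks for
ties. The scan handles missing calls by masked moment accumulation, which
is algebraically identical to dropping the lines pair-wise. Permutation
minima ignore NaN pairs; genes with no testable variant are dropped from
the family. The empirical-FDR grid defaults to the observed corrected-p
values plus zero, and a threshold of zero is attainable (genes whose
observed minimum beats all permutations). Clipping weights to [1e-3, 1e3]
bounds the influence of lowess extrapolation at the abundance extremes.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale: cohorts of 300–2,000
genes, 32 lines, 2 replicates, 200 permutations, 100 holdout lines. These
sizes keep every statistical property measurable (corrected-p resolution
0.005, binomial error on rejection rates below the asserted margins) while
the whole suite completes in a few minutes on one core. The same code paths
scale to transcriptome-wide input; only the permutation count and the trans
scan's variant panel are worth growing with the data.
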