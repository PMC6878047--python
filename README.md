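# wingqtl

Multi-layer omics analysis of organ-size variation on inbred *Drosophila*
panels: from raw RNA-seq counts of wing imaginal discs to the genetic
variants that predict between-line wing size.

The package is for quantitative geneticists working with homozygous
reference panels (DGRP-style lines) who want, in one tested toolkit:

* count preprocessing — library/gene filters, log-CPM with mean–variance
  precision weights, removal of the leading technical principal components,
  replicate averaging per line × sex, and reproducibility QC;
* **trait–expression association** in the three canonical forms: overall
  size association pooling sexes (type 1), sex-adjusted ANCOVA on size
  within sexes (type 2), and sex-only ANOVA for dimorphic expression
  (type 3), with Benjamini–Hochberg control per family;
* **cis-eQTL mapping** per sex: simple regression of line-level expression
  on the 0/1 alt indicator within ±100 kb of the gene body (MAF ≥ 10%),
  permutation min-p correction with one shared label shuffle per round,
  and the empirical FDR `FDR(t) = t·G / #{p_corr ≤ t}`;
* **mediator triangulation and prediction** — genes with a type-2
  association *and* an eQTL at 20% FDR whose variants also associate with
  the trait (p < 0.05) define a flow model in which each mediator-linked
  eQTL contributes a unit effect of sign
  `sign(β_eQTL) × sign(β_type2)`; a line's net score is the sum of those
  signed units over its alternate alleles, and the score is evaluated by
  rank correlation in-sample and by calibrated linear prediction (with
  50/95% intervals) on held-out lines;
* a **synthetic cohort generator** with planted ground truth (association
  types, cis-eQTLs, mediators, LD blocks, batch structure, sexually
  dimorphic phenotypes), so the whole pipeline is testable end-to-end with
  no downloads.

See `docs/methods.md` for the statistical models, defaults and their
rationale, and known limitations.

## Worked example

```python
from wingqtl.simulate import TruthSpec, simulate_cohort, extend_lines
from wingqtl.pipeline import run_pipeline, predict_new_lines

# 32 inbred lines, 300 genes; plant 20 type-2 genes of which 8 are
# mediators (cis-eQTL + SNP effect on wing size), 10 type-1, 10 type-3
spec = TruthSpec(n_type1=10, n_type2=20, n_type3=10, n_eqtl=20, n_mediators=8)
cohort = simulate_cohort(seed=1, truth_spec=spec)

result = run_pipeline(cohort, seed=2, n_perm=200)
cond = result.per_condition[("F", "absCS")]
print("confirmed type-3 genes:", int(result.classification["confirmed_type3"].sum()))
print("cis-eQTL genes at FDR<20% (F):", len(cond.fdr_selection.genes))
print("mediator-linked eQTL entries:", len(cond.model))
print("in-sample Spearman rho:", round(cond.evaluation["rho"], 3))

holdout_geno, holdout_pheno = extend_lines(cohort, 100, seed=3)
pred = predict_new_lines(cond, holdout_geno, holdout_pheno, list(cohort.geno.lines))
print("holdout Pearson r:", round(pred["r"], 3))
```

Output:

```
confirmed type-3 genes: 16
cis-eQTL genes at FDR<20% (F): 23
mediator-linked eQTL entries: 7
in-sample Spearman rho: 0.811
holdout Pearson r: 0.283
```

Reading: of the planted structure, the classifier recovers the sexually
dimorphic (type-3) genes, the permutation-corrected scan finds the
cis-regulated genes at the declared 20% FDR, and the seven mediator-linked
eQTLs that survive all three screens suffice to rank the 32 training lines
by wing size at ρ ≈ 0.81 and to predict 100 unseen lines with a positive,
significant correlation — the qualitative behaviour expected when a handful
of variants carry about half of the between-line variance.

The same stages are scriptable from a shell (`wingqtl simulate`,
`wingqtl preprocess`, `wingqtl associate`, `wingqtl qtl`,
`wingqtl mediate`, `wingqtl predict`); each subcommand reads and writes
plain TSV/VCF/YAML, so stages can be mixed with external tools.

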