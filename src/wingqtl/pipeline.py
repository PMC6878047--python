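"""End-to-end orchestration: counts -> expression -> associations ->
per-sex eQTL mapping -> mediator flow model -> line scoring and
(optionally) holdout prediction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import association, mediation, preprocess, qtl
from .datatypes import Cohort, ExpressionMatrix, GenotypeData
from .simulate import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class SexTraitResult:
    sex: str
    trait: str
    qtl_result: qtl.QtlResult
    fdr_selection: qtl.FdrSelection
    mediators: pd.DataFrame
    snp_screen: pd.DataFrame
    model: mediation.MediatorModel | None
    scores: pd.DataFrame | None
    evaluation: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    associations: dict[str, pd.DataFrame]
    classification: pd.DataFrame
    per_condition: dict[tuple[str, str], SexTraitResult]


def run_pipeline(
    cohort: Cohort,
    seed: int,
    n_perm: int = 200,
    fdr: float = 0.20,
    alpha: float = 0.05,
    window: int = 100_000,
    min_maf: float = 0.10,
    min_library_frac: float = 0.25,
    n_pcs: int = 2,
    sexes: tuple[str, ...] = ("F", "M"),
    traits: tuple[str, ...] = ("absCS", "relCS"),
    screen: bool = True,
) -> PipelineResult:
    """Run every stage on one cohort; mediator models are built per
    (sex, trait) condition, as the relevant genes and SNPs differ."""
    expr = preprocess.preprocess_counts(
        cohort.counts, min_library_frac=min_library_frac, n_pcs=n_pcs
    )
    fams = association.associate(expr, cohort.pheno)
    classification = association.classify_association_types(fams, fdr_threshold=fdr)

    geno = qtl.maf_filter(cohort.geno, min_maf)
    pairs = qtl.cis_pairs(geno.variants, cohort.genes, window)

    per_condition: dict[tuple[str, str], SexTraitResult] = {}
    for sex in sexes:
        sexpr = expr.sex_view(sex)
        res = qtl.permutation_adjust(
            sexpr, geno, pairs, n_perm=n_perm, seed=derive_seed(seed, f"perm-{sex}")
        )
        sel = qtl.empirical_fdr(res, target=fdr)
        for trait in traits:
            assoc2 = fams[f"type2_{trait}"]
            med = mediation.select_mediators(assoc2, res, sel, fdr=fdr)
            if screen and len(med):
                scr = mediation.snp_trait_screen(
                    geno, cohort.pheno, sorted(med["variant"].unique()), trait, sex, alpha
                )
                keep = set(scr.loc[scr["retained"], "variant"])
                med_kept = med[med["variant"].isin(keep)]
            else:
                scr = pd.DataFrame(columns=["variant", "beta", "p", "r2", "n", "retained"])
                med_kept = med
            model = mediation.build_flow_model(med_kept, sex, trait)
            scores = evaluation = calibration = None
            if len(model):
                scores = mediation.score_lines(model, geno)
                evaluation = mediation.evaluate_prediction(scores, cohort.pheno, trait, sex, "rank")
                calibration = mediation.evaluate_prediction(scores, cohort.pheno, trait, sex, "linear")
            per_condition[(sex, trait)] = SexTraitResult(
                sex=sex,
                trait=trait,
                qtl_result=res,
                fdr_selection=sel,
                mediators=med,
                snp_screen=scr,
                model=model if len(model) else None,
                scores=scores,
                evaluation=evaluation or {},
                calibration=calibration or {},
            )
    return PipelineResult(
        expression=expr,
        associations=fams,
        classification=classification,
        per_condition=per_condition,
    )


def predict_new_lines(
    condition: SexTraitResult,
    holdout_geno: GenotypeData,
    holdout_pheno: pd.DataFrame,
    training_lines: list[str],
) -> dict:
    """Score and evaluate a disjoint holdout panel with a fitted condition's
    model and linear calibration."""
    if condition.model is None:
        raise ValueError("condition has no mediator model")
    return mediation.predict_holdout(
        condition.model, condition.calibration, holdout_geno, holdout_pheno, training_lines
    )
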