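"""Mediator triangulation and the unit-sign additive flow model.

A mediator gene shows a triangular association: its expression maps to a
cis-eQTL (20% empirical FDR), its expression is associated with a wing-size
trait within sexes (type-2 association, 20% BH FDR), and the eQTL variants
themselves associate with the trait (nominal p < 0.05).  Each
mediator-linked eQTL then contributes one unit-strength signed effect per
line: sign(eQTL beta) x sign(type-2 slope) if the line carries the
alternate allele, zero for the reference allele, zero (but counted) for a
missing call.  The per-line sum of these units is the net score used to
predict between-line wing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeData
from .qtl import FdrSelection, QtlResult, significant_variants

logger = logging.getLogger(__name__)


def select_mediators(
    assoc_type2: pd.DataFrame,
    qtl_result: QtlResult,
    selection: FdrSelection,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Genes passing both FDR screens, with their linked eQTL variants.

    ``assoc_type2`` is one type-2 association family (same sex pooling and
    trait as the QTL scan's expression).  Returns one row per (gene,
    variant) with the eQTL beta and the type-2 slope carried forward.
    """
    expr_hits = set(assoc_type2.index[assoc_type2["fdr"] < fdr])
    eqtl_hits = set(qtl_result.genes.index[qtl_result.genes["fdr"] < fdr])
    genes = sorted(expr_hits & eqtl_hits)
    if not genes:
        logger.warning("no gene passes both the expression and eQTL FDR screens")
        return pd.DataFrame(columns=["gene", "variant", "beta_eqtl", "slope"])
    variants = significant_variants(qtl_result, selection)
    variants = variants[variants["gene"].isin(genes)]
    out = variants[["gene", "variant", "beta"]].rename(columns={"beta": "beta_eqtl"})
    out = out.assign(slope=assoc_type2.loc[out["gene"], "slope"].to_numpy())
    return out.reset_index(drop=True)


def snp_trait_screen(
    geno: GenotypeData,
    pheno: pd.DataFrame,
    variant_ids: list[str],
    trait: str,
    sex: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variant regression of the trait on the alt indicator, one sex.

    Returns every polymorphic variant with beta, p and R²; the ``retained``
    flag marks p < alpha.  Monomorphic variants are skipped.
    """
    ph = pheno[pheno["sex"] == sex].set_index("line")[trait]
    lines = [ln for ln in geno.lines if ln in ph.index]
    y_all = ph.loc[lines].to_numpy(dtype=float)
    rows = []
    for v in variant_ids:
        g = geno.calls.loc[lines, v].to_numpy(dtype=float)
        m = ~np.isnan(g)
        if m.sum() < 3 or np.nanstd(g[m]) == 0:
            continue
        res = stats.linregress(g[m], y_all[m])
        rows.append((v, res.slope, res.pvalue, res.rvalue**2, int(m.sum())))
    out = pd.DataFrame(rows, columns=["variant", "beta", "p", "r2", "n"])
    out["retained"] = out["p"] < alpha
    return out


@dataclass
class MediatorModel:
    """Signed unit effects of mediator-linked eQTLs for one (sex, trait)."""

    sex: str
    trait: str
    entries: pd.DataFrame  # variant, gene, eqtl_sign, trait_sign, net_sign

    def __len__(self) -> int:
        return len(self.entries)


def build_flow_model(
    selected: pd.DataFrame,
    sex: str,
    trait: str,
) -> MediatorModel:
    """Turn selected (gene, variant) pairs into unit-sign entries.

    eqtl_sign = sign of the eQTL beta (alt allele's effect on expression),
    trait_sign = sign of the type-2 slope (expression's association with the
    trait), net_sign = their product: the alt allele's predicted push on
    wing size.  Entries with a zero beta or slope carry no direction and are
    rejected.
    """
    rows = []
    for rec in selected.itertuples(index=False):
        if rec.beta_eqtl == 0 or rec.slope == 0 or np.isnan(rec.beta_eqtl) or np.isnan(rec.slope):
            logger.warning("entry (%s, %s) has a zero/undefined beta or slope; rejected", rec.gene, rec.variant)
            continue
        e = int(np.sign(rec.beta_eqtl))
        t = int(np.sign(rec.slope))
        rows.append((rec.variant, rec.gene, e, t, e * t))
    entries = pd.DataFrame(rows, columns=["variant", "gene", "eqtl_sign", "trait_sign", "net_sign"])
    return MediatorModel(sex=sex, trait=trait, entries=entries)


def score_lines(model: MediatorModel, geno: GenotypeData) -> pd.DataFrame:
    """Net score per line: sum of net signs over entries whose variant is
    called alternate; reference contributes zero; a missing call contributes
    zero and increments ``n_missing``."""
    if len(model) == 0:
        raise ValueError("mediator model has no entries")
    missing = set(model.entries["variant"]) - set(geno.variants.index)
    if missing:
        raise ValueError(f"variants absent from the genotype matrix: {sorted(missing)}")
    calls = geno.calls[model.entries["variant"].to_numpy()].to_numpy(dtype=float)  # (L, E)
    signs = model.entries["net_sign"].to_numpy(dtype=float)
    scored = np.nansum(np.nan_to_num(calls, nan=0.0) * signs, axis=1)
    n_missing = np.isnan(calls).sum(axis=1)
    return pd.DataFrame(
        {"net_score": scored.astype(int), "n_missing": n_missing.astype(int)},
        index=pd.Index(geno.lines, name="line"),
    )


def evaluate_prediction(
    scores: pd.DataFrame,
    pheno: pd.DataFrame,
    trait: str,
    sex: str,
    mode: str = "rank",
) -> dict:
    """Agreement between net scores and the observed trait for one sex.

    ``rank`` mode: Spearman rho and p.  ``linear`` mode: least-squares
    calibration trait ~ net_score with Pearson r, R² and 50%/95% prediction
    bands from the residual t distribution.
    """
    ph = pheno[pheno["sex"] == sex].set_index("line")[trait]
    lines = [ln for ln in scores.index if ln in ph.index]
    if len(lines) < 4:
        raise ValueError("need at least 4 scored lines with phenotype")
    x = scores.loc[lines, "net_score"].to_numpy(dtype=float)
    y = ph.loc[lines].to_numpy(dtype=float)
    if np.std(x) == 0:
        logger.warning("net scores are constant; correlation undefined")
        return {"mode": mode, "rho": np.nan, "p": np.nan, "n": len(lines)}
    if mode == "rank":
        rho, p = stats.spearmanr(x, y)
        return {"mode": "rank", "rho": float(rho), "p": float(p), "n": len(lines)}
    if mode != "linear":
        raise ValueError("mode must be 'rank' or 'linear'")
    res = stats.linregress(x, y)
    n = len(lines)
    resid = y - (res.intercept + res.slope * x)
    s = float(np.sqrt((resid**2).sum() / (n - 2)))
    bands = {
        f"band{int(level * 100)}": float(stats.t.ppf(0.5 + level / 2, n - 2) * s)
        for level in (0.50, 0.95)
    }
    return {
        "mode": "linear",
        "intercept": float(res.intercept),
        "slope": float(res.slope),
        "r": float(res.rvalue),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "resid_sd": s,
        "n": n,
        **bands,
    }


def predict_holdout(
    model: MediatorModel,
    calibration: dict,
    holdout_geno: GenotypeData,
    holdout_pheno: pd.DataFrame,
    training_lines: list[str],
) -> dict:
    """Apply a training-set calibration to unseen lines.

    The holdout must be disjoint from the training panel; predicted trait =
    intercept + slope * net_score.  Returns predictions plus Pearson r and
    p against the observed trait."""
    overlap = set(training_lines) & set(holdout_geno.lines)
    if overlap:
        raise ValueError(f"holdout lines overlap training lines: {sorted(overlap)}")
    scores = score_lines(model, holdout_geno)
    pred = calibration["intercept"] + calibration["slope"] * scores["net_score"]
    ph = holdout_pheno[holdout_pheno["sex"] == model.sex].set_index("line")[model.trait]
    lines = [ln for ln in scores.index if ln in ph.index]
    obs = ph.loc[lines].to_numpy(dtype=float)
    prd = pred.loc[lines].to_numpy(dtype=float)
    if np.std(prd) == 0:
        return {"predictions": pred, "r": np.nan, "p": np.nan, "n": len(lines)}
    r, p = stats.pearsonr(prd, obs)
    return {"predictions": pred, "r": float(r), "p": float(p), "n": len(lines)}
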