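"""Trait-expression association: three model types, BH correction and
association-type classification.

Model types (fit per gene on line x sex expression values, optionally
weighted):

* type 1 — expression ~ trait, pooling both sexes (captures variation that
  follows overall wing size, including the sexual dimorphism axis);
* type 2 — expression ~ sex + trait, a parallel-slopes ANCOVA isolating
  between-line size association within sexes;
* type 3 — expression ~ sex, one-way ANOVA for sexually dimorphic
  expression.

A gene whose expression is size-associated overall (type 1) but not within
either sex (no type-2 association with absCS or relCS) is "type-1
exclusive"; if its sex term is also significant it is a confirmed type-3
gene — dimorphic expression tracking the size difference between sexes
rather than between lines.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

MODEL_TYPES = (1, 2, 3)


def _align_pheno(expr: ExpressionMatrix, pheno: pd.DataFrame, trait: str) -> np.ndarray:
    ph = pheno.set_index(["line", "sex"])[trait]
    key = list(zip(expr.meta["line"], expr.meta["sex"]))
    return ph.loc[key].to_numpy(dtype=float)


def fit_trait_model(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    model_type: int,
    trait: str = "absCS",
) -> pd.DataFrame:
    """Weighted least squares per gene for one association type.

    Returns a frame indexed by gene with columns ``slope`` (trait
    coefficient, types 1/2), ``sex_effect`` (female-vs-male offset, types
    2/3), ``p`` (for the size term in types 1/2, the sex term in type 3),
    ``n`` and ``testable``.  Genes with fewer than 4 units or a constant
    regressor are flagged untestable (``p`` NaN) and excluded from FDR
    families downstream.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")
    y = expr.values.to_numpy(dtype=float)
    G, n = y.shape
    w = np.ones_like(y) if expr.weights is None else expr.weights.to_numpy(dtype=float)

    sexF = (expr.meta["sex"] == "F").to_numpy(dtype=float)
    if model_type == 3:
        X = np.column_stack([np.ones(n), sexF])
        test_col, slope_col, sex_col = 1, None, 1
        const_regressor = sexF.std() == 0
    else:
        t = _align_pheno(expr, pheno, trait)
        if model_type == 1:
            X = np.column_stack([np.ones(n), t])
            test_col, slope_col, sex_col = 1, 1, None
        else:
            X = np.column_stack([np.ones(n), sexF, t])
            test_col, slope_col, sex_col = 2, 2, 1
        const_regressor = t.std() == 0 or (model_type == 2 and sexF.std() == 0)

    p_params = X.shape[1]
    df_resid = n - p_params
    testable = (n >= 4) and (df_resid >= 1) and not const_regressor

    out = pd.DataFrame(
        {
            "slope": np.nan,
            "sex_effect": np.nan,
            "se": np.nan,
            "t": np.nan,
            "p": np.nan,
            "n": n,
            "testable": testable,
        },
        index=expr.genes,
    )
    out["model_type"] = model_type
    out["trait"] = trait if model_type != 3 else "none"
    if not testable:
        logger.warning("model type %d untestable (n=%d, constant regressor=%s)", model_type, n, const_regressor)
        return out

    # batched weighted normal equations: A_g = X' W_g X, b_g = X' W_g y_g
    A = np.einsum("np,gn,nq->gpq", X, w, X)
    b = np.einsum("np,gn->gp", X, w * y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # (G, p)
    resid = y - beta @ X.T
    rss = (w * resid**2).sum(axis=1)
    sigma2 = rss / df_resid
    Ainv = np.linalg.inv(A)
    var = sigma2[:, None] * np.einsum("gpp->gp", Ainv)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat[:, test_col]), df_resid)
    pvals = np.where(np.isfinite(tstat[:, test_col]), pvals, np.where(np.isnan(tstat[:, test_col]), np.nan, 0.0))

    if slope_col is not None:
        out["slope"] = beta[:, slope_col]
    if sex_col is not None:
        out["sex_effect"] = beta[:, sex_col]
    out["se"] = se[:, test_col]
    out["t"] = tstat[:, test_col]
    out["p"] = pvals
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted values (capped at 1, monotone in
    rank order).  NaN entries are excluded from the family size and stay NaN."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    ok = ~np.isnan(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def associate(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    layer: str = "RNA",
) -> dict[str, pd.DataFrame]:
    """All association families: type 1 (absCS), type 2 (absCS and relCS)
    and type 3, each with its own BH adjustment (FDR is controlled within
    one layer/model/trait family at a time, matching how thresholds are
    reported per analysis)."""
    fams = {
        "type1": fit_trait_model(expr, pheno, 1, "absCS"),
        "type2_absCS": fit_trait_model(expr, pheno, 2, "absCS"),
        "type2_relCS": fit_trait_model(expr, pheno, 2, "relCS"),
        "type3": fit_trait_model(expr, pheno, 3),
    }
    for df in fams.values():
        df["fdr"] = bh_adjust(df["p"])
        df["layer"] = layer
    return fams


def classify_association_types(
    records: dict[str, pd.DataFrame],
    fdr_threshold: float = 0.20,
) -> pd.DataFrame:
    """Set membership at the FDR threshold plus the exclusive-type-1 /
    confirmed-type-3 logic.

    ``exclusive_type1``: significant for type 1 but for neither type-2
    family.  ``confirmed_type3``: exclusive type 1 and the sex-only ANOVA is
    itself significant — the expression difference follows sex, not
    between-line size.
    """
    required = {"type1", "type2_absCS", "type2_relCS", "type3"}
    missing = required - set(records)
    if missing:
        raise ValueError(f"missing association families: {sorted(missing)}")
    genes = records["type1"].index
    out = pd.DataFrame(index=genes)
    for fam in sorted(required):
        fdr = records[fam].reindex(genes)["fdr"]
        absent = fdr.isna() & ~records[fam].reindex(genes)["testable"].fillna(False).astype(bool)
        if absent.any():
            logger.warning("%d genes untestable in family %s; treated as non-members", absent.sum(), fam)
        out[fam] = (fdr < fdr_threshold).fillna(False)
    out["exclusive_type1"] = out["type1"] & ~out["type2_absCS"] & ~out["type2_relCS"]
    out["confirmed_type3"] = out["exclusive_type1"] & out["type3"]
    return out


def spearman_size_correlation(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    trait: str = "absCS",
) -> pd.DataFrame:
    """Per-gene Spearman rank correlation with a size trait, pooled across
    sexes; p by the large-sample t approximation.  Constant genes get NaN."""
    if expr.values.shape[1] < 4:
        raise ValueError("need at least 4 units")
    t = _align_pheno(expr, pheno, trait)
    y = expr.values.to_numpy(dtype=float)
    rt = stats.rankdata(t)
    ry = stats.rankdata(y, axis=1)
    n = y.shape[1]
    rt_c = rt - rt.mean()
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((ry_c**2).sum(axis=1) * (rt_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ry_c @ rt_c) / denom
        tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    rho = np.where(denom > 0, rho, np.nan)
    p = np.where(denom > 0, p, np.nan)
    return pd.DataFrame({"rho": rho, "p": p}, index=expr.genes)
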