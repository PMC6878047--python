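"""Count preprocessing: sample/gene filters, log-CPM with precision weights,
batch principal-component removal and line x sex summarisation.

The stages mirror a standard bulk RNA-seq workflow for a replicated inbred
panel: shallow libraries are dropped, genes whose total count falls below
70% of the sample number are removed, counts become log2 CPM with a +0.5
count / +1 library offset, per-observation precision weights are derived
from a fitted mean-variance trend (count data are heteroscedastic on the
log scale), the first few sample-space principal components are regressed
out to absorb batch structure, and replicates are averaged per line x sex
with inverse-variance weight accumulation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datatypes import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_samples(counts: CountMatrix, min_library_frac: float = 0.25) -> CountMatrix:
    """Drop samples whose library size is below ``min_library_frac`` times
    the median library size."""
    if not (0 <= min_library_frac < 1):
        raise ValueError("min_library_frac must be in [0, 1)")
    libs = counts.library_sizes()
    cutoff = min_library_frac * libs.median()
    keep = libs >= cutoff
    if not keep.any():
        raise ValueError("sample filter removed every sample")
    removed = list(libs.index[~keep])
    if removed:
        logger.info("filter_samples removed %d samples: %s", len(removed), removed)
    return CountMatrix(counts.counts.loc[:, keep], counts.meta.loc[keep])


def filter_genes(counts: CountMatrix) -> CountMatrix:
    """Keep genes whose total count is at least 70% of the sample number.

    A gene with total count < 0.7 * n_samples cannot be quantified reliably
    at this depth and is removed.
    """
    n = counts.counts.shape[1]
    if n < 1:
        raise ValueError("need at least one sample")
    totals = counts.counts.sum(axis=1)
    keep = totals >= 0.7 * n
    return CountMatrix(counts.counts.loc[keep], counts.meta)


def log_cpm(counts: CountMatrix) -> pd.DataFrame:
    """log2 counts-per-million with the conventional 0.5/1 offsets."""
    libs = counts.library_sizes().to_numpy(dtype=float)
    vals = np.log2((counts.counts.to_numpy(dtype=float) + 0.5) / (libs + 1.0) * 1e6)
    return pd.DataFrame(vals, index=counts.genes, columns=counts.samples)


def log_cpm_weights(
    counts: CountMatrix,
    weighted: bool = True,
    lowess_frac: float = 0.5,
    weight_bounds: tuple[float, float] = (1e-3, 1e3),
) -> ExpressionMatrix:
    """Log-CPM values plus per-observation precision weights.

    The weights follow the mean-variance-trend idea used for count data on
    the log scale: expression is regressed on the line x sex design (group
    means), each gene contributes (average log2 count, sqrt(residual SD)) to
    a locally weighted scatterplot smoother, and each observation's weight
    is the trend prediction at its fitted log2 count raised to the -4th
    power — i.e. an inverse-variance weight — clipped to ``weight_bounds``.
    ``weighted=False`` returns unit weights (an ablation mode).
    """
    expr = log_cpm(counts)
    if not weighted:
        w = pd.DataFrame(1.0, index=expr.index, columns=expr.columns)
        return ExpressionMatrix(expr, counts.meta.copy(), w)

    y = expr.to_numpy()
    groups = counts.meta["line"].astype(str) + ":" + counts.meta["sex"].astype(str)
    codes = np.asarray(pd.Categorical(groups).codes, dtype=int)
    n_groups = int(codes.max()) + 1
    # fitted values from the group-mean (line x sex) model, per observation
    sums = np.zeros((y.shape[0], n_groups))
    cnt = np.bincount(codes, minlength=n_groups).astype(float)
    for g in range(n_groups):
        sums[:, g] = y[:, codes == g].sum(axis=1)
    gmeans = sums / cnt
    fitted = gmeans[:, codes]
    resid = y - fitted
    df_resid = y.shape[1] - n_groups
    if df_resid < 1:
        logger.warning("no residual degrees of freedom; falling back to unit weights")
        w = pd.DataFrame(1.0, index=expr.index, columns=expr.columns)
        return ExpressionMatrix(expr, counts.meta.copy(), w)
    sd = np.sqrt((resid**2).sum(axis=1) / df_resid)

    libs = counts.library_sizes().to_numpy(dtype=float)
    mean_logcount = np.log2(counts.counts.to_numpy(dtype=float) + 0.5).mean(axis=1)
    trend = sm.nonparametric.lowess(
        np.sqrt(np.maximum(sd, 1e-8)), mean_logcount, frac=lowess_frac, return_sorted=True
    )
    tx, ty = trend[:, 0], trend[:, 1]

    # per-observation predicted sqrt-SD at the observation's fitted log2 count
    fitted_logcount = fitted + np.log2(libs + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(pred, 1e-8) ** 4
    w = np.clip(w, *weight_bounds)
    wdf = pd.DataFrame(w, index=expr.index, columns=expr.columns)
    return ExpressionMatrix(expr, counts.meta.copy(), wdf)


def remove_batch_pcs(expr: ExpressionMatrix, k: int = 2) -> ExpressionMatrix:
    """Regress the top-``k`` sample-space principal components out of every
    gene, restoring each gene's mean.

    PCs are computed on gene-standardised expression so a few high-variance
    genes cannot dominate the directions; the residual matrix is orthogonal
    to the retained scores.
    """
    if k <= 0:
        logger.warning("remove_batch_pcs called with k <= 0; returning input unchanged")
        return expr
    n_units = expr.values.shape[1]
    if k >= n_units:
        raise ValueError("k must be smaller than the number of units")

    y = expr.values.to_numpy()
    mu = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (y - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    # right singular vectors = sample-space PC scores
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[:k].T  # (units, k); mean-zero because genes were centred

    X = np.column_stack([np.ones(n_units), scores])
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y - (X @ beta).T
    cleaned = resid + mu
    out = pd.DataFrame(cleaned, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.meta.copy(), None if expr.weights is None else expr.weights.copy())


def summarize_line_sex(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicates per line x sex; weights add (inverse-variance of a
    mean of independent observations)."""
    meta = expr.meta
    key = meta["line"].astype(str) + ":" + meta["sex"].astype(str)
    groups = key.groupby(key).groups

    cols, vals, wts, meta_rows = [], [], [], []
    for unit, samples in groups.items():
        line, sex = unit.split(":")
        cols.append(unit)
        vals.append(expr.values[list(samples)].mean(axis=1))
        if expr.weights is not None:
            wts.append(expr.weights[list(samples)].sum(axis=1))
        meta_rows.append((line, sex, len(samples)))
    values = pd.concat(vals, axis=1)
    values.columns = cols
    weights = None
    if expr.weights is not None:
        weights = pd.concat(wts, axis=1)
        weights.columns = cols
    out_meta = pd.DataFrame(
        meta_rows, columns=["line", "sex", "n_replicates"], index=pd.Index(cols, name="unit")
    )
    return ExpressionMatrix(values, out_meta, weights)


def preprocess_counts(
    counts: CountMatrix,
    min_library_frac: float = 0.25,
    n_pcs: int = 2,
    weighted: bool = True,
) -> ExpressionMatrix:
    """Full preprocessing chain: sample filter, gene filter, log-CPM with
    precision weights, batch-PC removal, line x sex summarisation."""
    kept = filter_genes(filter_samples(counts, min_library_frac))
    expr = log_cpm_weights(kept, weighted=weighted)
    if n_pcs > 0:
        expr = remove_batch_pcs(expr, n_pcs)
    return summarize_line_sex(expr)


# ---------------------------------------------------------------------------
# QC / concordance


def _pair_relation(meta: pd.DataFrame, a: str, b: str) -> str:
    la, sa = meta.loc[a, "line"], meta.loc[a, "sex"]
    lb, sb = meta.loc[b, "line"], meta.loc[b, "sex"]
    if la == lb and sa == sb:
        return "replicate"
    if la == lb:
        return "same-line-other-sex"
    return "non-replicate"


def concordance_report(
    expr: ExpressionMatrix,
    other_layer: ExpressionMatrix | None = None,
) -> dict:
    """Reproducibility and cross-layer agreement statistics.

    Within-layer mode: Spearman rho for every sample pair, grouped into
    replicates (same line, same sex), same-line-other-sex, and
    non-replicates, with group medians.  Cross-layer mode (``other_layer``
    given): per-gene Spearman rho across shared units, the median rho, and
    the fraction of genes with a significantly positive correlation
    (p < 0.05).  Ties get average ranks.
    """
    if other_layer is None:
        units = list(expr.units)
        if len(units) < 2:
            raise ValueError("need at least 2 samples for a concordance report")
        rho, _ = stats.spearmanr(expr.values.to_numpy())
        rho = np.atleast_2d(rho)
        pairs: dict[str, list[float]] = {
            "replicate": [],
            "same-line-other-sex": [],
            "non-replicate": [],
        }
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                pairs[_pair_relation(expr.meta, units[i], units[j])].append(rho[i, j])
        return {
            "mode": "within",
            "pairs": pairs,
            "median": {k: (float(np.median(v)) if v else np.nan) for k, v in pairs.items()},
        }

    shared_genes = expr.genes.intersection(other_layer.genes)
    shared_units = expr.units.intersection(other_layer.units)
    if len(shared_units) < 3:
        return {
            "mode": "cross",
            "per_gene": pd.DataFrame(columns=["rho", "p"]),
            "median_rho": np.nan,
            "frac_positive_significant": np.nan,
            "note": "fewer than 3 shared units; per-gene rho undefined",
        }
    a = expr.values.loc[shared_genes, shared_units].to_numpy()
    b = other_layer.values.loc[shared_genes, shared_units].to_numpy()
    rhos = np.full(len(shared_genes), np.nan)
    ps = np.full(len(shared_genes), np.nan)
    for i in range(len(shared_genes)):
        if np.std(a[i]) == 0 or np.std(b[i]) == 0:
            continue
        r, p = stats.spearmanr(a[i], b[i])
        rhos[i], ps[i] = r, p
    per_gene = pd.DataFrame({"rho": rhos, "p": ps}, index=shared_genes)
    ok = per_gene.dropna()
    return {
        "mode": "cross",
        "per_gene": per_gene,
        "median_rho": float(ok["rho"].median()) if len(ok) else np.nan,
        "frac_positive_significant": float(((ok["rho"] > 0) & (ok["p"] < 0.05)).mean())
        if len(ok)
        else np.nan,
    }
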