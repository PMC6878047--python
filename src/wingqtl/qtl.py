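"""cis/trans QTL mapping on an inbred panel with permutation min-p
correction and empirical FDR.

Per sex, line-level expression of each gene is regressed on the 0/1 alt
indicator of every variant in scope (simple least squares; lines with a
missing call drop out of that pair).  Multiple testing across the variants
of a gene is corrected by permuting line labels: one shared shuffle per
round is applied to the whole expression matrix (preserving gene-gene
correlation), the minimum nominal p per gene is recorded each round, and
the corrected p is the fraction of permutation minima smaller than the
observed minimum.  Family-level significance uses the empirical FDR
``FDR(t) = t * G / #{corrected_p <= t}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeData

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filters and scope


def maf_filter(geno: GenotypeData, min_maf: float = 0.10) -> GenotypeData:
    """Drop variants with minor allele frequency below ``min_maf`` (computed
    over non-missing lines; the boundary value is kept)."""
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = geno.maf()
    keep = maf.index[maf >= min_maf]
    out = geno.subset_variants(keep)
    out.variants = out.variants.assign(maf=maf.loc[keep])
    return out


def classify_cis_trans(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Scope of every (gene, variant) pair: cis iff same chromosome and
    position within ``[start - window, end + window]`` (inclusive), else
    trans."""
    unknown = set(variants["chrom"]) - set(genes["chrom"])
    if unknown:
        raise ValueError(f"variants on chromosomes absent from the annotation: {sorted(unknown)}")
    rows = []
    for g in genes.itertuples(index=False):
        same = variants["chrom"].to_numpy() == g.chrom
        pos = variants["pos"].to_numpy()
        cis = same & (pos >= g.start - window) & (pos <= g.end + window)
        scope = np.where(cis, "cis", "trans")
        rows.append(pd.DataFrame({
            "gene": g.gene_id,
            "variant": variants["variant_id"].to_numpy(),
            "scope": scope,
        }))
    return pd.concat(rows, ignore_index=True)


def cis_pairs(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Only the cis (gene, variant) pairs — the scan's working set."""
    rows = []
    by_chrom = {c: sub.sort_values("pos") for c, sub in variants.groupby("chrom")}
    for g in genes.itertuples(index=False):
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, g.start - window, side="left")
        hi = np.searchsorted(pos, g.end + window, side="right")
        if hi > lo:
            rows.append(pd.DataFrame({
                "gene": g.gene_id,
                "variant": sub["variant_id"].to_numpy()[lo:hi],
            }))
    if not rows:
        return pd.DataFrame(columns=["gene", "variant"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# the scan engine


class _PairScan:
    """Vectorised per-pair regression with missing-call masking.

    Holds the genotype columns for every (gene, variant) pair, sorted by
    gene, with masked first/second moments precomputed so that scanning an
    (observed or permuted) expression matrix is a handful of dense array
    operations.
    """

    def __init__(self, expr: ExpressionMatrix, geno: GenotypeData, pairs: pd.DataFrame):
        lines = [ln for ln in expr.units if ln in set(geno.lines)]
        if len(lines) < len(expr.units):
            logger.warning("dropping %d expression units without genotypes", len(expr.units) - len(lines))
        self.lines = lines
        self.E = expr.values[lines].to_numpy(dtype=float)  # (G, n)
        self.gene_ids = list(expr.genes)
        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

        pairs = pairs[pairs["gene"].isin(gene_pos) & pairs["variant"].isin(geno.variants.index)]
        pairs = pairs.assign(_g=pairs["gene"].map(gene_pos)).sort_values(["_g", "variant"], kind="stable")
        self.pairs = pairs.reset_index(drop=True)
        self.pair_gene = self.pairs["_g"].to_numpy()

        calls = geno.calls.loc[lines, self.pairs["variant"].to_numpy()].to_numpy(dtype=float)  # (n, P)
        self.M = (~np.isnan(calls)).astype(float)
        self.Gz = np.nan_to_num(calls, nan=0.0)
        self.n_eff = self.M.sum(axis=0)
        self.Sg = self.Gz.sum(axis=0)
        self.Sgg = (self.Gz**2).sum(axis=0)
        with np.errstate(invalid="ignore"):
            self.var_g = self.Sgg - self.Sg**2 / np.where(self.n_eff > 0, self.n_eff, np.nan)

        # reduceat boundaries for per-gene minima over pairs
        self.scan_genes = np.unique(self.pair_gene)
        self.starts = np.searchsorted(self.pair_gene, self.scan_genes, side="left")

    def _stats(self, perm: np.ndarray | None):
        E = self.E if perm is None else self.E[:, perm]
        Y = E[self.pair_gene].T  # (n, P): each pair's own gene expression
        Sy = (self.M * Y).sum(axis=0)
        Syy = (self.M * Y**2).sum(axis=0)
        Sgy = (self.Gz * Y).sum(axis=0)
        n = self.n_eff
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = Sgy - self.Sg * Sy / n
            var_y = Syy - Sy**2 / n
            beta = cov / self.var_g
            r2 = cov**2 / (self.var_g * var_y)
            r2 = np.clip(r2, 0.0, 1.0)
            df = n - 2
            tstat2 = r2 * df / (1.0 - r2)
        valid = (self.var_g > 0) & (var_y > 0) & (df >= 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(
                np.isfinite(tstat2),
                2.0 * stats.t.sf(np.sqrt(np.maximum(tstat2, 0.0)), np.maximum(df, 1)),
                0.0,
            )
        p = np.where(valid, p, np.nan)
        beta = np.where(valid, beta, np.nan)
        r = np.sign(cov) * np.sqrt(r2)
        r = np.where(valid, r, np.nan)
        return beta, r, p

    def scan(self, perm: np.ndarray | None = None) -> pd.DataFrame:
        beta, r, p = self._stats(perm)
        return pd.DataFrame({
            "gene": self.pairs["gene"].to_numpy(),
            "variant": self.pairs["variant"].to_numpy(),
            "beta": beta,
            "r": r,
            "p": p,
            "n": self.n_eff.astype(int),
        })

    def min_p(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Per-gene minimum nominal p (NaN pairs ignored); aligned with
        ``self.scan_genes``."""
        _, _, p = self._stats(perm)
        filled = np.where(np.isnan(p), np.inf, p)
        mins = np.minimum.reduceat(filled, self.starts)
        return np.where(np.isfinite(mins), mins, np.nan)


def nominal_scan(
    expr: ExpressionMatrix,
    geno: GenotypeData,
    pairs: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    scope: str = "cis",
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-pair simple regression of line-level expression (one sex) on the
    alt indicator.  ``pairs`` may be given directly; otherwise they are
    derived from the annotation with the ±``window`` cis rule.  Monomorphic
    pairs (after missing removal) come back with NaN p and are counted in
    the log."""
    if pairs is None:
        if genes is None:
            raise ValueError("provide either pairs or a gene annotation")
        if scope == "cis":
            pairs = cis_pairs(geno.variants, genes, window)
        elif scope == "trans":
            allp = classify_cis_trans(geno.variants, genes, window)
            pairs = allp[allp["scope"] == "trans"][["gene", "variant"]]
        else:
            allp = classify_cis_trans(geno.variants, genes, window)
            pairs = allp[["gene", "variant"]]
    scan = _PairScan(expr, geno, pairs)
    rec = scan.scan()
    skipped = int(rec["p"].isna().sum())
    if skipped:
        logger.info("nominal_scan skipped %d monomorphic/degenerate pairs", skipped)
    return rec


# ---------------------------------------------------------------------------
# permutation correction


@dataclass
class QtlResult:
    """Nominal records plus gene-level permutation summaries.

    ``genes`` is indexed by gene id with columns min_p, corrected_p, fdr
    (monotone empirical-FDR q-value) and n_variants.  ``perm_min`` holds the
    per-round minima (genes x rounds) so variant-level thresholds can be
    reconstructed at any corrected-p cutoff.
    """

    records: pd.DataFrame
    genes: pd.DataFrame
    perm_min: np.ndarray
    n_perm: int
    counting: str = "plain"
    extras: dict = field(default_factory=dict)


def permutation_adjust(
    expr: ExpressionMatrix,
    geno: GenotypeData,
    pairs: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    counting: str = "plain",
) -> QtlResult:
    """Permutation min-p correction, one shared line shuffle per round.

    ``corrected_p`` = (number of permutation minima strictly smaller than
    the observed minimum) / n_perm, which can be exactly zero; pass
    ``counting='add-one'`` for the positively biased (k+1)/(n+1) variant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if counting not in ("plain", "add-one"):
        raise ValueError("counting must be 'plain' or 'add-one'")
    if n_perm < 100:
        logger.warning("n_perm=%d gives a corrected-p resolution of %.3f", n_perm, 1 / n_perm)
    scan = _PairScan(expr, geno, pairs)
    obs_records = scan.scan()
    obs_min = scan.min_p()

    rng = np.random.default_rng(seed)
    n_lines = len(scan.lines)
    perm_min = np.empty((len(scan.scan_genes), n_perm))
    for r in range(n_perm):
        perm = rng.permutation(n_lines)
        perm_min[:, r] = scan.min_p(perm)

    with np.errstate(invalid="ignore"):
        smaller = (perm_min < obs_min[:, None]).sum(axis=1)
    if counting == "plain":
        corrected = smaller / n_perm
    else:
        corrected = (smaller + 1) / (n_perm + 1)
    corrected = np.where(np.isnan(obs_min), np.nan, corrected)

    gene_ids = [scan.gene_ids[i] for i in scan.scan_genes]
    n_var = obs_records.groupby("gene", sort=False)["variant"].size().reindex(gene_ids).to_numpy()
    genes = pd.DataFrame(
        {"min_p": obs_min, "corrected_p": corrected, "n_variants": n_var},
        index=pd.Index(gene_ids, name="gene"),
    )
    genes["fdr"] = _qvalues(genes["corrected_p"])
    return QtlResult(records=obs_records, genes=genes, perm_min=perm_min, n_perm=n_perm, counting=counting)


def _qvalues(corrected_p: pd.Series) -> pd.Series:
    """Gene-level empirical-FDR q-value: min over thresholds t >= cp of
    t * G / #{cp <= t}."""
    cp = corrected_p.dropna().sort_values()
    G = len(cp)
    if G == 0:
        return pd.Series(np.nan, index=corrected_p.index)
    ranks = np.arange(1, G + 1)
    fdr = cp.to_numpy() * G / ranks
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    q = pd.Series(np.minimum(fdr, 1.0), index=cp.index)
    return q.reindex(corrected_p.index)


@dataclass
class FdrSelection:
    curve: pd.DataFrame
    threshold: float | None
    genes: list[str]
    target: float


def empirical_fdr(
    result: QtlResult,
    target: float = 0.20,
    grid: np.ndarray | None = None,
) -> FdrSelection:
    """Empirical FDR curve and the largest corrected-p threshold meeting the
    target.

    FDR(t) = (t * G) / #{corrected_p <= t} with G the family size; grid
    points where nothing passes are undefined and skipped.
    """
    cp = result.genes["corrected_p"].dropna()
    G = len(cp)
    if grid is None:
        grid = np.unique(np.concatenate([[0.0], cp.to_numpy()]))
    rows = []
    for t in np.sort(np.asarray(grid, dtype=float)):
        n_pass = int((cp <= t).sum())
        if n_pass == 0:
            continue
        rows.append((t, n_pass, t * G / n_pass))
    curve = pd.DataFrame(rows, columns=["threshold", "n_pass", "fdr"])
    ok = curve[curve["fdr"] <= target]
    if ok.empty:
        logger.warning("no corrected-p threshold reaches the %.0f%% FDR target", 100 * target)
        return FdrSelection(curve=curve, threshold=None, genes=[], target=target)
    thr = float(ok["threshold"].max())
    sig = list(cp.index[cp <= thr])
    return FdrSelection(curve=curve, threshold=thr, genes=sig, target=target)


def significant_variants(result: QtlResult, selection: FdrSelection) -> pd.DataFrame:
    """Variant-level calls for genes passing the empirical-FDR cut.

    Each significant gene's nominal threshold is the permutation quantile
    matching the corrected-p cutoff (the (k+1)-th smallest permutation
    minimum, k = floor(t * n_perm)); all of the gene's tested variants with
    nominal p at or below that threshold are reported.
    """
    if selection.threshold is None or not selection.genes:
        return result.records.iloc[0:0].copy()
    k = int(np.floor(selection.threshold * result.n_perm))
    k = min(k, result.n_perm - 1)
    sorted_min = np.sort(result.perm_min, axis=1)
    gene_index = {g: i for i, g in enumerate(result.genes.index)}
    out = []
    for g in selection.genes:
        thr = sorted_min[gene_index[g], k]
        sub = result.records[result.records["gene"] == g]
        out.append(sub[sub["p"] <= thr])
    if not out:
        return result.records.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# summaries


def qtl_density_profile(
    qtls: pd.DataFrame,
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    bin_size: int = 5_000,
    span: int = 100_000,
) -> pd.DataFrame:
    """eQTLs per kb against position relative to the transcript start and
    end, measured in the direction of transcription (upstream negative).

    Returns one row per (anchor in {TSS, TES}, bin) with the raw count and
    the per-kb density; a QTL contributes one assignment to each anchor
    whose signed distance falls inside ±``span``.
    """
    if qtls.empty:
        raise ValueError("no QTLs to profile")
    vt = variants.set_index("variant_id")
    gt = genes.set_index("gene_id")
    pos = vt.loc[qtls["variant"], "pos"].to_numpy()
    g = gt.loc[qtls["gene"]]
    strand = (g["strand"] == "+").to_numpy()
    tss = np.where(strand, g["start"], g["end"]).astype(float)
    tes = np.where(strand, g["end"], g["start"]).astype(float)
    sign = np.where(strand, 1.0, -1.0)
    d_tss = (pos - tss) * sign
    d_tes = (pos - tes) * sign

    edges = np.arange(-span, span + bin_size, bin_size)
    rows = []
    for anchor, d in (("TSS", d_tss), ("TES", d_tes)):
        inside = d[(d >= -span) & (d <= span)]
        hist, _ = np.histogram(inside, bins=edges)
        for left, count in zip(edges[:-1], hist):
            rows.append((anchor, int(left), int(left + bin_size), int(count), count / (bin_size / 1_000)))
    return pd.DataFrame(rows, columns=["anchor", "bin_start", "bin_end", "count", "per_kb"])


def sex_overlap(qtl_f: pd.DataFrame, qtl_m: pd.DataFrame) -> dict:
    """Shared/specific counts and fractions for variants and for genes
    between the female and male eQTL sets."""
    out = {}
    for level, col in (("variants", "variant"), ("genes", "gene")):
        f = set(qtl_f[col]) if col in qtl_f else set()
        m = set(qtl_m[col]) if col in qtl_m else set()
        shared = f & m
        out[level] = {
            "n_female": len(f),
            "n_male": len(m),
            "n_shared": len(shared),
            "frac_of_female": len(shared) / len(f) if f else np.nan,
            "frac_of_male": len(shared) / len(m) if m else np.nan,
        }
    return out
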