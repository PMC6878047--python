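"""Synthetic cohort generator for an inbred-line wing-size study.

The generator emulates the statistical structure of a multi-layer omics
study on a panel of fully inbred fly lines:

* a compact genome annotation with non-overlapping gene models,
* homozygous biallelic genotypes with a chosen minor-allele-frequency
  spectrum, local linkage blocks and optional missing calls,
* sexually dimorphic wing-size phenotypes (females larger) whose
  between-line variance is partly driven by planted mediator SNPs,
* negative-binomial RNA-seq counts whose latent log2 means carry planted
  sex effects (type-3), within-sex size associations (type-2), combined
  effects (type-1), cis-eQTL effects and a low-rank batch shift.

Every random draw descends from one master seed through labelled hashing,
so a cohort is bitwise reproducible and submodules can be re-run alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Cohort, CountMatrix, GenotypeData, TruthTable


def derive_seed(master: int, label: str) -> int:
    """Deterministic child seed for a labelled subcomponent (< 2**31)."""
    return (int(master) * 2654435761 + zlib.crc32(label.encode())) % (2**31 - 1)


def _rng(master: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, label))


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    n_genes: int,
    n_variants: int,
    chrom_lengths: dict[str, int],
    seed: int,
    gene_length: tuple[int, int] = (1_000, 10_000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gene annotation and variant positions.

    Genes are placed in disjoint slots along each chromosome (so intervals
    never overlap); variant positions are uniform over the genome.  Returns
    ``(genes, variants)`` where ``genes`` has columns gene_id, chrom, start,
    end, strand (1-based, inclusive) and ``variants`` has variant_id, chrom,
    pos, ref, alt.
    """
    if n_genes < 1 or n_variants < 1:
        raise ValueError("n_genes and n_variants must be >= 1")
    if not chrom_lengths:
        raise ValueError("chrom_lengths must not be empty")
    rng = _rng(seed, "genome")

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    # genes per chromosome, proportional to length
    alloc = np.floor(lengths / lengths.sum() * n_genes).astype(int)
    for i in np.argsort(-lengths):
        if alloc.sum() >= n_genes:
            break
        alloc[i] += n_genes - alloc.sum()
    rows = []
    gid = 0
    for chrom, n_c in zip(chroms, alloc):
        if n_c == 0:
            continue
        L = chrom_lengths[chrom]
        slot = L // n_c
        if slot < gene_length[0] + 2:
            raise ValueError(
                f"chromosome {chrom} (length {L}) too short for {n_c} genes "
                f"of minimum length {gene_length[0]}"
            )
        for j in range(n_c):
            lo = j * slot + 1
            glen = int(rng.integers(gene_length[0], min(gene_length[1], slot - 1) + 1))
            start = int(rng.integers(lo, lo + slot - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{gid:04d}", chrom, start, start + glen - 1, strand))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    # uniform variant positions, unique per chromosome
    probs = lengths / lengths.sum()
    counts = rng.multinomial(n_variants, probs)
    vrows = []
    bases = np.array(list("ACGT"))
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        pos = set()
        while len(pos) < n_c:
            pos.update(rng.integers(1, chrom_lengths[chrom] + 1, size=n_c - len(pos)).tolist())
        for p in sorted(pos):
            ref, alt = rng.choice(4, size=2, replace=False)
            vrows.append((f"{chrom}_{p}_SNP", chrom, int(p), bases[ref], bases[alt]))
    variants = pd.DataFrame(vrows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return genes, variants


# ---------------------------------------------------------------------------
# genotypes


def generate_genotypes(
    variants: pd.DataFrame,
    n_lines: int,
    seed: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    ld_block: int = 20_000,
    ld_corr: float = 0.9,
    missing_rate: float = 0.0,
) -> GenotypeData:
    """Simulate homozygous calls for ``n_lines`` inbred lines.

    Variants falling in the same ``ld_block``-bp window of a chromosome share
    a haplotype pattern: the first variant of the block is drawn Bernoulli at
    an alt frequency sampled from ``maf_range`` and the others copy it,
    flipping each line to an independent draw with probability
    ``1 - ld_corr``.  ``ld_corr = 1`` gives identical call vectors within a
    block; ``ld_corr = 0`` gives independent variants.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed, "genotypes")

    lines = [f"line{i:03d}" for i in range(n_lines)]
    calls = np.empty((n_lines, len(variants)), dtype=float)
    block_key = list(zip(variants["chrom"], variants["pos"] // int(ld_block)))
    prev_key = None
    anchor = None
    for j, key in enumerate(block_key):
        freq = rng.uniform(lo, hi)
        fresh = rng.binomial(1, freq, size=n_lines).astype(float)
        if key == prev_key and anchor is not None and ld_corr > 0:
            keep = rng.random(n_lines) >= (1.0 - ld_corr)
            col = np.where(keep, anchor, fresh)
        else:
            col = fresh
            anchor = col
        calls[:, j] = col
        prev_key = key
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = np.nan

    df = pd.DataFrame(calls, index=lines, columns=variants["variant_id"].to_numpy())
    vt = variants.set_index("variant_id", drop=False)
    geno = GenotypeData(df, vt)
    geno.variants = geno.variants.assign(maf=geno.maf())
    return geno


# ---------------------------------------------------------------------------
# truth plumbing


@dataclass
class TruthSpec:
    """How many genes to plant per association type, and effect scales.

    Effects are on the latent log2-expression scale; ``type2_slope`` is per
    unit of within-sex absCS deviation.  ``n_mediators`` genes get a type-2
    effect, a cis-eQTL of effect ``eqtl_beta`` and a planted SNP effect of
    ``mediator_trait_effect`` absCS units on the phenotype, with the trait
    effect sign matched to sign(eqtl beta) * sign(expression slope).
    """

    n_type1: int = 0
    n_type2: int = 0
    n_type3: int = 0
    n_eqtl: int = 0
    n_mediators: int = 0
    sex_effect: float = 1.0
    type2_slope: float = 0.15
    eqtl_beta: float = 1.0
    mediator_trait_effect: float = 2.0


def build_truth(
    genes: pd.DataFrame,
    geno: GenotypeData,
    spec: TruthSpec,
    seed: int,
    cis_window: int = 100_000,
    tss_concentration: float = 0.8,
) -> TruthTable:
    """Assign planted effects to genes and variants.

    Planted cis-eQTL variants are preferentially drawn near the transcript
    start/end (within 10 kb of TSS or TES with probability
    ``tss_concentration``), mirroring where regulatory variants concentrate.
    Mediator genes are a subset of the type-2 genes; each receives one
    eQTL variant that also perturbs the phenotype.
    """
    rng = _rng(seed, "truth")
    n_special = spec.n_type1 + spec.n_type2 + spec.n_type3
    if n_special > len(genes):
        raise ValueError("more planted genes than genes in the annotation")
    if spec.n_mediators > spec.n_type2:
        raise ValueError("mediators must be a subset of type-2 genes")

    order = rng.permutation(len(genes))
    gt = genes.set_index("gene_id")
    ids = genes["gene_id"].to_numpy()[order]
    t1 = ids[: spec.n_type1]
    t2 = ids[spec.n_type1 : spec.n_type1 + spec.n_type2]
    t3 = ids[spec.n_type1 + spec.n_type2 : n_special]

    gdf = pd.DataFrame(
        {"assoc_type": "none", "sex_effect": 0.0, "line_slope": 0.0},
        index=pd.Index(genes["gene_id"], name="gene_id"),
    )
    signs = lambda n: rng.choice([-1.0, 1.0], size=n)  # noqa: E731
    gdf.loc[t1, "assoc_type"] = "1"
    gdf.loc[t1, "sex_effect"] = spec.sex_effect * signs(len(t1))
    gdf.loc[t1, "line_slope"] = spec.type2_slope * signs(len(t1))
    gdf.loc[t2, "assoc_type"] = "2"
    gdf.loc[t2, "line_slope"] = spec.type2_slope * signs(len(t2))
    gdf.loc[t3, "assoc_type"] = "3"
    gdf.loc[t3, "sex_effect"] = spec.sex_effect * signs(len(t3))

    # eQTL placement: mediator genes first (guaranteed), then others
    mediator_genes = list(t2[: spec.n_mediators])
    n_extra = max(spec.n_eqtl - len(mediator_genes), 0)
    pool = [g for g in ids if g not in set(mediator_genes)]
    eqtl_genes = mediator_genes + pool[:n_extra]

    vt = geno.variants
    erows, mrows = [], []
    for g in eqtl_genes:
        row = gt.loc[g]
        same = vt[vt["chrom"] == row["chrom"]]
        window = same[
            (same["pos"] >= row["start"] - cis_window) & (same["pos"] <= row["end"] + cis_window)
        ]
        usable = window[(window["maf"] >= 0.1)]
        if usable.empty:
            usable = window
        if usable.empty:
            continue
        if rng.random() < tss_concentration:
            anchor = row["start"] if row["strand"] == "+" else row["end"]
            d = (usable["pos"] - anchor).abs()
            near = usable[d <= 10_000]
            pick = near if len(near) else usable
        else:
            pick = usable
        variant = pick["variant_id"].iloc[int(rng.integers(len(pick)))]
        beta = spec.eqtl_beta * float(rng.choice([-1.0, 1.0]))
        erows.append((g, variant, beta))
        if g in mediator_genes:
            slope = gdf.loc[g, "line_slope"]
            net = np.sign(beta) * np.sign(slope)
            mrows.append((g, variant, int(net), spec.mediator_trait_effect * net))

    truth = TruthTable(
        genes=gdf,
        eqtls=pd.DataFrame(erows, columns=["gene", "variant", "beta"]),
        mediators=pd.DataFrame(mrows, columns=["gene", "variant", "net_sign", "trait_beta"]),
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(
    lines: list[str],
    geno: GenotypeData,
    truth: TruthTable,
    seed: int,
    baseline: float = 160.0,
    sex_dimorphism: float = 15.0,
    line_sd: float = 2.0,
    noise_sd: float = 0.5,
    iod_corr: float = 0.5,
) -> pd.DataFrame:
    """Simulate wing-size phenotypes, one row per line x sex.

    absCS = baseline + sex_dimorphism * [sex == F] + planted SNP effects
    + line effect + noise.  IOD is built with partial correlation
    ``iod_corr`` to the line component of absCS, and relCS is the per-sex
    residual of absCS regressed on IOD with the per-sex mean restored
    (keeping centroid-size units and the sex offset).
    """
    if line_sd < 0:
        raise ValueError("line_sd must be non-negative")
    rng = _rng(seed, "phenotypes")
    n = len(lines)
    line_eff = rng.normal(0.0, line_sd, size=n)

    snp_eff = np.zeros(n)
    if len(truth.mediators):
        calls = geno.calls.loc[lines, truth.mediators["variant"].to_numpy()].to_numpy()
        betas = truth.mediators["trait_beta"].to_numpy()
        snp_eff = np.nansum(calls * betas, axis=1)

    rows = []
    for sex in ("F", "M"):
        sexF = 1.0 if sex == "F" else 0.0
        abscs = (
            baseline
            + sex_dimorphism * sexF
            + snp_eff
            + line_eff
            + rng.normal(0.0, noise_sd, size=n)
        )
        iod_line = iod_corr * line_eff + np.sqrt(max(1 - iod_corr**2, 0.0)) * rng.normal(
            0.0, line_sd, size=n
        )
        iod = 40.0 + 3.0 * sexF + 0.25 * iod_line + rng.normal(0.0, 0.1, size=n)
        for i, line in enumerate(lines):
            rows.append((line, sex, abscs[i], iod[i]))
    pheno = pd.DataFrame(rows, columns=["line", "sex", "absCS", "IOD"])
    pheno["relCS"] = compute_relcs(pheno)
    return pheno


def compute_relcs(pheno: pd.DataFrame) -> pd.Series:
    """Body-size-adjusted centroid size: per-sex residual of absCS on IOD,
    shifted back by the per-sex mean absCS."""
    out = pd.Series(np.nan, index=pheno.index)
    for _, idx in pheno.groupby("sex").groups.items():
        x = pheno.loc[idx, "IOD"].to_numpy()
        y = pheno.loc[idx, "absCS"].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.loc[idx] = y - X @ beta + y.mean()
    return out


# ---------------------------------------------------------------------------
# expression counts


def generate_expression(
    truth: TruthTable,
    pheno: pd.DataFrame,
    geno: GenotypeData,
    seed: int,
    n_replicates: int = 2,
    batch_effect: float = 0.8,
    dispersion: float = 0.05,
    gene_line_sd: float = 0.2,
    base_log2_range: tuple[float, float] = (3.0, 9.0),
) -> CountMatrix:
    """Draw negative-binomial counts for every line x sex x replicate.

    Per-gene latent log2 mean = baseline + sex effect (types 1, 3)
    + slope * within-sex absCS deviation (types 1, 2) + eQTL beta * alt call
    (planted eQTLs) + technical batch terms + per-line biological noise.
    The technical structure has rank two — a library factor (replicates
    alternate between two library preparations) and a processing-cohort
    factor (lines split into two handling cohorts), each with independent
    per-gene loadings — emulating a study whose two leading expression
    principal components are technical and are regressed out downstream.
    Dispersion is shared per gene (variance = mu + dispersion * mu**2).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    genes = truth.genes.index.to_numpy()
    unknown = set(truth.eqtls.get("gene", pd.Series(dtype=str))) - set(genes)
    if unknown:
        raise ValueError(f"truth references unknown genes: {sorted(unknown)}")
    if len(truth.eqtls):
        missing_v = set(truth.eqtls["variant"]) - set(geno.variants.index)
        if missing_v:
            raise ValueError(f"truth references unknown variants: {sorted(missing_v)}")

    rng = _rng(seed, "expression")
    lines = list(geno.lines)
    ph = pheno.set_index(["line", "sex"])

    sample_ids, meta_rows = [], []
    cohort_of = {line: "c1" if i < len(lines) // 2 else "c2" for i, line in enumerate(lines)}
    for line in lines:
        for sex in ("F", "M"):
            for rep in range(1, n_replicates + 1):
                sid = f"{line}_{sex}_r{rep}"
                lib = f"lib{1 + (rep - 1) % 2}"
                sample_ids.append(sid)
                meta_rows.append((line, sex, rep, f"{lib}-{cohort_of[line]}"))
    meta = pd.DataFrame(
        meta_rows, columns=["line", "sex", "replicate", "batch"], index=pd.Index(sample_ids, name="sample")
    )

    n_s = len(sample_ids)
    G = len(genes)
    base = rng.uniform(*base_log2_range, size=G)
    lib_load = rng.normal(0.0, batch_effect, size=G)
    cohort_load = rng.normal(0.0, batch_effect, size=G)
    is_lib2 = meta["batch"].str.startswith("lib2").to_numpy(dtype=float)
    is_c2 = meta["batch"].str.endswith("c2").to_numpy(dtype=float)

    # within-sex absCS deviation per sample
    abscs = np.array([ph.loc[(r.line, r.sex), "absCS"] for r in meta.itertuples()])
    sex_arr = meta["sex"].to_numpy()
    dev = abscs.copy()
    for sex in ("F", "M"):
        m = sex_arr == sex
        dev[m] = abscs[m] - abscs[m].mean()
    sexF = (sex_arr == "F").astype(float)

    sex_eff = truth.genes["sex_effect"].to_numpy()
    slope = truth.genes["line_slope"].to_numpy()
    atype = truth.genes["assoc_type"].to_numpy()
    use_sex = np.isin(atype, ["1", "3"]).astype(float)
    use_slope = np.isin(atype, ["1", "2"]).astype(float)

    latent = (
        base[:, None]
        + (use_sex * sex_eff)[:, None] * sexF[None, :]
        + (use_slope * slope)[:, None] * dev[None, :]
        + lib_load[:, None] * is_lib2[None, :]
        + cohort_load[:, None] * is_c2[None, :]
    )

    if len(truth.eqtls):
        line_idx = {ln: i for i, ln in enumerate(lines)}
        gene_idx = {g: i for i, g in enumerate(genes)}
        sample_line = np.array([line_idx[ln] for ln in meta["line"]])
        for g, v, beta in truth.eqtls.itertuples(index=False):
            alt = np.nan_to_num(geno.calls[v].to_numpy(), nan=0.0)
            latent[gene_idx[g], :] += beta * alt[sample_line]

    # biological line noise, shared by replicates of the same line x sex
    line_noise = rng.normal(0.0, gene_line_sd, size=(G, len(lines), 2))
    sexi = (sex_arr == "M").astype(int)
    sample_line = np.array([lines.index(ln) for ln in meta["line"]])
    latent += line_noise[:, sample_line, sexi[np.arange(n_s)]]

    mu = np.exp2(latent)
    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    cdf = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return CountMatrix(cdf, meta)


# ---------------------------------------------------------------------------
# one-call cohort


def simulate_cohort(
    seed: int,
    n_genes: int = 300,
    n_variants: int = 3_000,
    n_lines: int = 32,
    chrom_lengths: dict[str, int] | None = None,
    truth_spec: TruthSpec | None = None,
    n_replicates: int = 2,
    maf_range: tuple[float, float] = (0.1, 0.5),
    ld_block: int = 20_000,
    ld_corr: float = 0.9,
    missing_rate: float = 0.01,
    batch_effect: float = 0.8,
    dispersion: float = 0.05,
    gene_line_sd: float = 0.2,
    sex_dimorphism: float = 15.0,
    line_sd: float = 2.0,
    pheno_noise_sd: float = 0.5,
) -> Cohort:
    """Generate a full synthetic study from one master seed."""
    if chrom_lengths is None:
        chrom_lengths = {"2L": 12_000_000, "2R": 12_000_000, "X": 8_000_000}
    if truth_spec is None:
        truth_spec = TruthSpec()
    genes, variants = generate_genome(n_genes, n_variants, chrom_lengths, seed)
    geno = generate_genotypes(
        variants,
        n_lines,
        seed,
        maf_range=maf_range,
        ld_block=ld_block,
        ld_corr=ld_corr,
        missing_rate=missing_rate,
    )
    truth = build_truth(genes, geno, truth_spec, seed)
    pheno = generate_phenotypes(
        list(geno.lines),
        geno,
        truth,
        seed,
        sex_dimorphism=sex_dimorphism,
        line_sd=line_sd,
        noise_sd=pheno_noise_sd,
    )
    counts = generate_expression(
        truth,
        pheno,
        geno,
        seed,
        n_replicates=n_replicates,
        batch_effect=batch_effect,
        dispersion=dispersion,
        gene_line_sd=gene_line_sd,
    )
    return Cohort(genes=genes, geno=geno, pheno=pheno, counts=counts, truth=truth)


def extend_lines(
    cohort: Cohort,
    n_new_lines: int,
    seed: int,
    line_prefix: str = "holdout",
) -> tuple[GenotypeData, pd.DataFrame]:
    """Draw genotypes and phenotypes for additional lines from the same
    generative process (same variants, same planted truth) — used for
    holdout prediction."""
    variants = cohort.geno.variants.reset_index(drop=True)
    geno = generate_genotypes(variants, n_new_lines, derive_seed(seed, "holdout-geno"))
    geno.calls.index = [f"{line_prefix}{i:03d}" for i in range(n_new_lines)]
    pheno = generate_phenotypes(
        list(geno.lines), geno, cohort.truth, derive_seed(seed, "holdout-pheno")
    )
    return geno, pheno
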