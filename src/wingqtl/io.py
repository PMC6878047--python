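"""Reading and writing the pipeline's on-disk formats.

Genotypes travel either as VCF (GT fields ``0/0`` / ``1/1`` / ``./.`` —
the panel is inbred, heterozygous calls are invalid) or as a flat
DGRP-style TSV (chrom, pos, ref, alt, one 0/1/NA column per line).  All
other tables (counts, sample metadata, phenotypes, annotation, expression,
truth) are TSV, and a cohort is tied together by a small YAML file listing
the relative paths.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from cyvcf2 import VCF

from .datatypes import Cohort, CountMatrix, ExpressionMatrix, GenotypeData, TruthTable


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_vcf(geno: GenotypeData, path: str | Path, chrom_lengths: dict[str, int] | None = None) -> None:
    path = str(path)
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    chroms = list(dict.fromkeys(geno.variants["chrom"]))
    for c in chroms:
        length = None if chrom_lengths is None else chrom_lengths.get(c)
        header.contigs.add(c, length=length)
    for line in geno.lines:
        header.add_sample(line)
    with pysam.VariantFile(path, "w", header=header) as out:
        for vid, row in geno.variants.iterrows():
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
                id=vid,
            )
            calls = geno.calls[vid]
            for line in geno.lines:
                c = calls[line]
                if np.isnan(c):
                    rec.samples[line]["GT"] = (None, None)
                else:
                    a = int(c)
                    rec.samples[line]["GT"] = (a, a)
                rec.samples[line].phased = False
            out.write(rec)


def read_genotypes_vcf(path: str | Path) -> GenotypeData:
    vcf = VCF(str(path))
    lines = list(vcf.samples)
    cols, vrows = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"only biallelic records are supported (got {v.ID})")
        gt = np.asarray(v.gt_types, dtype=float)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        if (gt == 1).any():
            raise ValueError(f"heterozygous call in an inbred panel at {v.ID}")
        col = np.where(gt == 0, 0.0, np.where(gt == 3, 1.0, np.nan))
        vid = v.ID or f"{v.CHROM}_{v.POS}_SNP"
        cols.append(pd.Series(col, index=lines, name=vid))
        vrows.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
    calls = pd.concat(cols, axis=1)
    variants = pd.DataFrame(vrows, columns=["variant_id", "chrom", "pos", "ref", "alt"]).set_index(
        "variant_id", drop=False
    )
    geno = GenotypeData(calls, variants)
    geno.variants = geno.variants.assign(maf=geno.maf())
    return geno


def write_genotypes_tsv(geno: GenotypeData, path: str | Path) -> None:
    df = geno.variants[["chrom", "pos", "ref", "alt"]].copy()
    calls = geno.calls.T  # variants x lines
    out = pd.concat([df, calls], axis=1)
    out.to_csv(path, sep="\t", index_label="variant_id")


def read_genotypes_tsv(path: str | Path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    variants = df[meta_cols].copy()
    variants["variant_id"] = variants.index
    calls = df.drop(columns=meta_cols).T.astype(float)
    geno = GenotypeData(calls, variants[["variant_id", *meta_cols]])
    geno.variants = geno.variants.assign(maf=geno.maf())
    return geno


# ---------------------------------------------------------------------------
# tables


def write_expression(expr: ExpressionMatrix, values_path: str | Path, weights_path: str | Path | None = None) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    if weights_path is not None and expr.weights is not None:
        expr.weights.to_csv(weights_path, sep="\t", index_label="gene_id")


def read_expression(
    values_path: str | Path,
    meta_path: str | Path,
    weights_path: str | Path | None = None,
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    weights = None
    if weights_path is not None:
        weights = pd.read_csv(weights_path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(values, meta, weights)


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort(cohort: Cohort, outdir: str | Path, chrom_lengths: dict[str, int] | None = None) -> Path:
    """Write every cohort table plus a YAML manifest; returns the manifest
    path.  The manifest flags the body-size adjustment convention used for
    relCS (per-sex residual on IOD), since that definition is a modelling
    choice."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": "annotation.tsv",
        "genotypes_vcf": "genotypes.vcf",
        "genotypes_tsv": "genotypes.tsv",
        "counts": "counts.tsv",
        "samples": "samples.tsv",
        "phenotypes": "phenotypes.tsv",
        "truth_genes": "truth_genes.tsv",
        "truth_eqtls": "truth_eqtls.tsv",
        "truth_mediators": "truth_mediators.tsv",
    }
    cohort.genes.to_csv(outdir / paths["annotation"], sep="\t", index=False)
    write_genotypes_vcf(cohort.geno, outdir / paths["genotypes_vcf"], chrom_lengths)
    write_genotypes_tsv(cohort.geno, outdir / paths["genotypes_tsv"])
    cohort.counts.counts.to_csv(outdir / paths["counts"], sep="\t", index_label="gene_id")
    cohort.counts.meta.to_csv(outdir / paths["samples"], sep="\t", index_label="sample")
    cohort.pheno.to_csv(outdir / paths["phenotypes"], sep="\t", index=False)
    cohort.truth.genes.to_csv(outdir / paths["truth_genes"], sep="\t", index_label="gene_id")
    cohort.truth.eqtls.to_csv(outdir / paths["truth_eqtls"], sep="\t", index=False)
    cohort.truth.mediators.to_csv(outdir / paths["truth_mediators"], sep="\t", index=False)
    manifest = {
        "files": paths,
        "conventions": {
            "relCS": "per-sex residual of absCS regressed on IOD, per-sex mean restored",
            "genotype_coding": "0=ref, 1=alt, NA=missing (homozygous inbred lines)",
        },
    }
    mpath = outdir / "cohort.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_cohort(manifest_path: str | Path) -> Cohort:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    p = manifest["files"]
    genes = pd.read_csv(root / p["annotation"], sep="\t")
    geno = read_genotypes_tsv(root / p["genotypes_tsv"])
    counts = pd.read_csv(root / p["counts"], sep="\t", index_col="gene_id")
    meta = pd.read_csv(root / p["samples"], sep="\t", index_col="sample")
    pheno = pd.read_csv(root / p["phenotypes"], sep="\t")
    truth = TruthTable(
        genes=pd.read_csv(root / p["truth_genes"], sep="\t", index_col="gene_id"),
        eqtls=pd.read_csv(root / p["truth_eqtls"], sep="\t"),
        mediators=pd.read_csv(root / p["truth_mediators"], sep="\t"),
    )
    truth.genes["assoc_type"] = truth.genes["assoc_type"].astype(str)
    return Cohort(genes=genes, geno=geno, pheno=pheno, counts=CountMatrix(counts, meta), truth=truth)
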