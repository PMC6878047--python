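"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Inbred lines are homozygous, so genotype calls are coded 0 (reference),
  1 (alternate) and ``NaN`` (missing / unassigned).  A diploid 0/1/2 coding
  would be degenerate for such a panel.
* Expression matrices are genes x units, where a unit is either a sequencing
  sample or a line-by-sex average.  Optional precision weights share the
  matrix shape and are strictly positive where present.
* Phenotypes carry exactly one row per line-by-sex combination with the wing
  size traits ``absCS`` (absolute centroid size), ``IOD`` (interocular
  distance, the body-size reference) and ``relCS`` (body-size adjusted
  centroid size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("F", "M")
TRAITS = ("absCS", "relCS")


@dataclass
class CountMatrix:
    """Raw RNA-seq counts (genes x samples) plus per-sample metadata.

    ``meta`` is indexed by sample id and must carry columns
    ``line``, ``sex``, ``replicate`` and ``batch``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.columns]
        missing = {"line", "sex", "replicate", "batch"} - set(self.meta.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Real-valued expression (genes x units) with optional precision weights."""

    values: pd.DataFrame
    meta: pd.DataFrame
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must share the shape of values")
            if (self.weights.to_numpy() <= 0).any():
                raise ValueError("precision weights must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def units(self) -> pd.Index:
        return self.values.columns

    def subset_units(self, units: pd.Index | list[str]) -> "ExpressionMatrix":
        w = None if self.weights is None else self.weights[units]
        return ExpressionMatrix(self.values[units], self.meta.loc[units], w)

    def sex_view(self, sex: str) -> "ExpressionMatrix":
        """Units of one sex, re-labelled by line id (for per-sex QTL scans)."""
        units = self.meta.index[self.meta["sex"] == sex]
        sub = self.subset_units(units)
        lines = sub.meta["line"].tolist()
        sub.values.columns = lines
        if sub.weights is not None:
            sub.weights.columns = lines
        sub.meta = sub.meta.set_index("line", drop=False)
        return sub


@dataclass
class GenotypeData:
    """Homozygous genotype calls for a panel of inbred lines.

    ``calls``: lines x variants with entries 0.0 / 1.0 / NaN.
    ``variants``: indexed by variant id with columns chrom, pos, ref, alt, maf.
    """

    calls: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.columns.equals(self.variants.index):
            raise ValueError("calls columns must match the variant table index")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1 or missing")

    @property
    def lines(self) -> pd.Index:
        return self.calls.index

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant over non-missing lines."""
        p = self.calls.mean(axis=0, skipna=True)
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, ids: pd.Index | list[str]) -> "GenotypeData":
        return GenotypeData(self.calls[ids], self.variants.loc[ids])

    def subset_lines(self, lines: list[str]) -> "GenotypeData":
        return GenotypeData(self.calls.loc[lines], self.variants)


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic cohort.

    genes: per gene ``assoc_type`` in {"1","2","3","none"}, ``sex_effect``
    (log2 units, type 1/3), ``line_slope`` (log2 units per trait unit,
    type 1/2).
    eqtls: one row per planted (gene, variant) with ``beta`` in log2 units.
    mediators: mediator-linked eQTLs with the planted trait effect and the
    expected net sign (sign of eQTL beta times sign of expression slope).
    """

    genes: pd.DataFrame
    eqtls: pd.DataFrame = field(default_factory=pd.DataFrame)
    mediators: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        if len(self.mediators):
            typed = self.genes.loc[self.mediators["gene"].unique(), "assoc_type"]
            if not (typed == "2").all():
                raise ValueError("every planted mediator gene must carry a type-2 effect")
            planted = set(zip(self.eqtls["gene"], self.eqtls["variant"]))
            for g, v in zip(self.mediators["gene"], self.mediators["variant"]):
                if (g, v) not in planted:
                    raise ValueError(f"mediator pair ({g}, {v}) lacks a planted eQTL")


@dataclass
class Cohort:
    """A self-contained synthetic study: annotation, genotypes, phenotypes,
    counts and the planted truth."""

    genes: pd.DataFrame
    geno: GenotypeData
    pheno: pd.DataFrame
    counts: CountMatrix
    truth: TruthTable
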