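import numpy as np
import pandas as pd
import pytest

from wingqtl.datatypes import GenotypeData
from wingqtl.simulate import TruthSpec, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Mid-size cohort with all association types, eQTLs and mediators."""
    spec = TruthSpec(n_type1=10, n_type2=20, n_type3=10, n_eqtl=20, n_mediators=8)
    return simulate_cohort(seed=7, truth_spec=spec)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects (pure noise expression)."""
    return simulate_cohort(seed=13, n_genes=400, n_variants=2000, truth_spec=TruthSpec())


def make_geno(calls: np.ndarray, chrom="2L", start_pos=1000, spacing=1000) -> GenotypeData:
    """Small hand-built genotype panel; calls is lines x variants with NaN for
    missing."""
    n_lines, n_var = calls.shape
    lines = [f"L{i}" for i in range(n_lines)]
    ids = [f"{chrom}_{start_pos + j * spacing}_SNP" for j in range(n_var)]
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": [start_pos + j * spacing for j in range(n_var)],
            "ref": "A",
            "alt": "T",
        }
    ).set_index("variant_id", drop=False)
    geno = GenotypeData(pd.DataFrame(calls.astype(float), index=lines, columns=ids), variants)
    geno.variants = geno.variants.assign(maf=geno.maf())
    return geno
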