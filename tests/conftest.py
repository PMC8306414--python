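import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from abokit.data import GenotypeMatrix
from abokit.simulate import (
    SimulationConfig,
    noiseless_three_tag_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """921 samples, three perfect anchor tags, zero typing error."""
    return simulate_cohort(noiseless_three_tag_config(rng_seed=20210921))


@pytest.fixture(scope="session")
def noiseless_design(noiseless_cohort):
    """Minor-allele dosage matrix (O-, A-, B-tag) and serotypes."""
    from abokit.assoc import code_additive

    gm = noiseless_cohort.genotypes()
    dosages, alleles = code_additive(gm)
    sero = noiseless_cohort.samples["serotype"].to_numpy(dtype=object)
    return dosages, alleles, sero, gm


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-like cohort: redundant tags, 2% typing error, relatives,
    light missingness, null background."""
    cfg = SimulationConfig(n_samples=500, n_null_snps=1500, rng_seed=77)
    return simulate_cohort(cfg)


def make_genotype_matrix(dosages, snp_ids=None, chrom="1", sample_ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    sample_ids = sample_ids or [f"S{i + 1:04d}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(dosages, sample_ids, snps)
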