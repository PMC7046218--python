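import numpy as np
import pandas as pd
import pytest

from prfr import (
    GenotypeMatrix,
    PhenotypeTable,
    SNPInfo,
    SimulationConfig,
    simulate_cohort,
)


def make_matrix(dosages, snp_prefix="s", chrom="1"):
    """GenotypeMatrix from a plain nested list / array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    snps = [SNPInfo(f"{snp_prefix}{j + 1}", chrom, 1000 * (j + 1)) for j in range(p)]
    samples = [f"i{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages, snps, samples)


def make_phenotypes(outcomes, sample_ids=None, **covariates):
    outcomes = np.asarray(outcomes, dtype=int)
    if sample_ids is None:
        sample_ids = [f"i{i + 1}" for i in range(outcomes.size)]
    df = pd.DataFrame({"sample_id": sample_ids, "outcome": outcomes})
    for name, values in covariates.items():
        df[name] = values
    return PhenotypeTable(df)


@pytest.fixture(scope="session")
def small_signal_cohort():
    """400 samples x 300 SNPs, 5 strongly causal — enough signal for model tests."""
    cfg = SimulationConfig(
        n_individuals=400,
        n_snps=300,
        n_causal=5,
        causal_effects=[float(np.log(2.5))] * 5,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """300 samples x 400 SNPs, no causal architecture."""
    cfg = SimulationConfig(n_individuals=300, n_snps=400, n_causal=0, seed=13)
    return simulate_cohort(cfg)
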