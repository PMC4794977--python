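import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_tables, oracles

from autozyg.genotype_io import MISSING, GenotypeDataset
from autozyg.synthetic_data import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """60 individuals x 3000 SNPs on 2 chromosomes, mild missingness."""
    cfg = SimConfig(n_cases=30, n_controls=30, n_snps=3000, n_chroms=2, seed=11)
    dataset, truth = simulate_genotypes(cfg)
    pheno = np.array([1] * 30 + [0] * 30)
    dataset.samples["phenotype"] = pheno
    return dataset, truth


def make_dataset(calls, spacing_bp=15_000, chrom=1, phenotype=None):
    """Hand-built dataset from an (n_samples, n_snps) call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(m)],
            "chrom": chrom,
            "bp": np.arange(1, m + 1) * spacing_bp,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "sex": 1,
            "phenotype": phenotype if phenotype is not None else -9,
        }
    )
    return GenotypeDataset(variants, samples, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
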