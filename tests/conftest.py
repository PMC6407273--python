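import numpy as np
import pandas as pd
import pytest

from spirogwas import SimConfig, default_reference, simulate_cohort, classify_obstruction
from spirogwas.cohort import Cohort


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def small_cohort(reference):
    """2,000 never-smokers × 300 null SNPs — shared by scan-level tests."""
    cfg = SimConfig(n_subjects=2000, n_snps=300, stratum_mix=1.0,
                    maf_range=(0.1, 0.5), missing_genotype_rate=0.01, seed=2024)
    return simulate_cohort(cfg, reference)


@pytest.fixture(scope="session")
def small_labels(small_cohort, reference):
    return classify_obstruction(small_cohort, reference)


@pytest.fixture(scope="session")
def mixed_cohort(reference):
    """Both smoking strata, a handful of SNPs, for interaction/stratum tests."""
    cfg = SimConfig(n_subjects=3000, n_snps=40, stratum_mix=0.5,
                    maf_range=(0.2, 0.5), missing_genotype_rate=0.0, seed=77)
    return simulate_cohort(cfg, reference)


@pytest.fixture(scope="session")
def mixed_labels(mixed_cohort, reference):
    return classify_obstruction(mixed_cohort, reference)


def make_cohort(genotypes, *, fev1=None, fvc=None, pack_years=None,
                sex=None, age=None, height=None, chromosome=None, position=None):
    """Hand-built cohort around an explicit genotype matrix (tests only)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    subjects = pd.DataFrame({
        "id": [f"T{i:04d}" for i in range(n)],
        "sex": sex if sex is not None else ["male"] * n,
        "age": age if age is not None else np.full(n, 50.0),
        "height": height if height is not None else np.full(n, 175.0),
        "smoking_status": "never",
        "pack_years": pack_years if pack_years is not None else np.zeros(n),
        "current_smoker": False,
        "fev1": fev1 if fev1 is not None else np.full(n, 3.5),
        "fvc": fvc if fvc is not None else np.full(n, 4.5),
        "asthma": False,
    })
    snp_info = pd.DataFrame({
        "snp_id": [f"m{j}" for j in range(m)],
        "chromosome": chromosome if chromosome is not None else np.ones(m, dtype=int),
        "position": position if position is not None else 1000 * (np.arange(m) + 1),
        "allele1": ["A"] * m,
        "allele2": ["G"] * m,
    })
    return Cohort(subjects=subjects, genotypes=genotypes, snp_info=snp_info)
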