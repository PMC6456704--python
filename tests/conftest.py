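from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from episcan.genotype_io import CohortTable, GenotypeMatrix

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


def make_genotypes(dosages, ids=None, chrom="6", pos=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    ids = ids or [f"m{j + 1}" for j in range(m)]
    markers = pd.DataFrame({
        "id": ids, "chrom": chrom,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "B",
    })
    return GenotypeMatrix(dosages, markers, [f"s{i + 1}" for i in range(n)])


def make_cohort(status, covariates=None) -> CohortTable:
    status = np.asarray(status, dtype=np.int8)
    n = status.shape[0]
    cov = (pd.DataFrame(covariates) if covariates is not None
           else pd.DataFrame(index=range(n)))
    return CohortTable([f"s{i + 1}" for i in range(n)], status, cov)


def null_two_snp_cohort(rng, n=2000, n_covars=3,
                        betas=(0.3, -0.25)) -> tuple[GenotypeMatrix, CohortTable]:
    """Two markers with main effects + covariates, no interaction."""
    g1 = rng.binomial(2, 0.3, n).astype(np.int8)
    g2 = rng.binomial(2, 0.4, n).astype(np.int8)
    C = rng.standard_normal((n, n_covars))
    gamma = np.linspace(0.2, -0.15, n_covars)
    eta = -0.2 + betas[0] * g1 + betas[1] * g2 + C @ gamma
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    gm = make_genotypes(np.column_stack([g1, g2]), ids=["s1", "s2"])
    cohort = make_cohort(y, {f"c{k + 1}": C[:, k] for k in range(n_covars)})
    return gm, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def example_results_path() -> Path:
    return DATA_DIR / "uc_mhc_pairs.tsv"
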