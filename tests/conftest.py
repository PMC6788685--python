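import numpy as np
import pandas as pd
import pytest

from proteodiscover.containers import ProteinMatrix
from proteodiscover.qc import log10_transform
from proteodiscover.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    """A compact cohort with planted effects, shared across tests."""
    return SimConfig(
        n_pd=60, n_nc=40, n_proteins=200, n_planted=10, delta=0.15,
        censor_frac_target=0.1, n_high_cv=8, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_log_matrix(small_cohort):
    matrix, meta, truth = small_cohort
    return log10_transform(matrix), meta, truth


@pytest.fixture()
def toy_matrix():
    """Tiny handmade raw matrix for arithmetic-level checks."""
    data = pd.DataFrame(
        {
            "p1": [100.0, 200.0, 400.0],
            "p2": [1000.0, 2000.0, 4000.0],
            "p3": [10.0, 20.0, 40.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    data.columns.name = "protein_id"
    return ProteinMatrix(data, scale="raw")
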