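import numpy as np
import pytest

from adipomets import CohortConfig, generate, classify_mets_table, compute_index_table


@pytest.fixture(scope="session")
def cohort_2k():
    """A moderate synthetic cohort shared across read-only tests."""
    df, truth = generate(CohortConfig(n=2000, seed=0), with_truth=True)
    return df, truth


@pytest.fixture(scope="session")
def analyzed_2k(cohort_2k):
    df, _ = cohort_2k
    idx = compute_index_table(df)
    mets = classify_mets_table(df)
    return df, idx, mets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
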