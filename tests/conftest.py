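import numpy as np
import pytest

from ipqsar import attach_activities, make_profile_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-signal dataset shared by unit tests: 15 compounds,
    8 residues (48 features), 3 informative columns."""
    records, matrix, table, truth = make_profile_dataset(
        n_compounds=15, n_residues=8, n_informative=3,
        noise_sd=0.2, sparsity=0.7, seed=42,
    )
    _, y = attach_activities(matrix, table)
    return records, matrix, table, truth, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
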