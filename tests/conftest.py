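import numpy as np
import pytest

from neoconn.report import extract_panels
from neoconn.simulate import CohortConfig, simulate_dataset


@pytest.fixture(scope="session")
def atlas90():
    from neoconn.atlas import generate_atlas
    return generate_atlas(seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced default-structure cohort: 20 subjects, short scan."""
    cfg = CohortConfig(n_subjects=20, n_timepoints=64, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_panels(small_dataset):
    return extract_panels(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
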