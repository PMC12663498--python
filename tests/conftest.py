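import numpy as np
import pytest

from cardioscore.scoring import DEFAULT_CONFIG
from cardioscore.synthetic_data import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 400-subject synthetic cohort shared across tests."""
    cfg = SyntheticCohortConfig(n=400, seed=7)
    return generate_cohort(cfg, DEFAULT_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
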