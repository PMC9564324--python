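import numpy as np
import pytest

from wtint.annotation import generate_annotation
from wtint.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def annotation():
    return generate_annotation(seed=11, n_genes=200)


@pytest.fixture(scope="session")
def small_cohort():
    """12-tumor cohort covering every CN pattern, with RNA for all."""
    cfg = CohortConfig(seed=42, n_tumors=12, n_genes=300)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
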