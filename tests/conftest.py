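import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endolight as el

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small null phantom with all three groups, shared across unit tests."""
    cfg = el.PhantomConfig(
        shape=(12, 12, 12), n_control=6, n_case=6, n_sibling=6, seed=7
    )
    dataset, truth = el.generate_phantom_cohort(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_mask(tiny_cohort):
    dataset, _ = tiny_cohort
    return el.build_mask(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
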