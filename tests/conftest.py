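import numpy as np
import pytest
from hypothesis import settings

from apindel import SimConfig, enumerate_label_space, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def space():
    return enumerate_label_space()


@pytest.fixture(scope="session")
def small_dataset(space):
    """120 synthetic records at default generator conditions."""
    cfg = SimConfig(n_targets=120, seed=7)
    return generate_dataset(cfg, space)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
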