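import numpy as np
import pytest
from hypothesis import settings

import csityping as ct
from csityping.simgen import make_stimuli

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return ct.DesignConfig()


@pytest.fixture(scope="session")
def stimuli(default_config):
    """Synthetic stimulus inventory in the standard 24x5 + 40 shape."""
    return make_stimuli(default_config, seed=1)


@pytest.fixture(scope="session")
def trial_list(stimuli, default_config):
    return ct.generate_list(stimuli, default_config, seed=42)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic experiment reused by several test modules."""
    cfg = ct.DesignConfig(
        n_categories=6,
        n_fillers=10,
        n_blocks=2,
        categories_per_block=3,
        fillers_per_block=5,
    )
    return ct.simulate_experiment(cfg, n_subjects=6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
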