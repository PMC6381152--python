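import numpy as np
import pytest

from circschema import DesignConfig, default_generative_params, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Simulated experiment at full block structure but 6 participants/group."""
    cfg = DesignConfig(n_per_group=6, seed=11)
    return simulate_experiment(cfg, default_generative_params())


@pytest.fixture(scope="session")
def default_config():
    return DesignConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
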