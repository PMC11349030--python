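import numpy as np
import pytest

from bilingam.simulate import SimulationConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_study():
    """A small 3-group family used by several test modules."""
    cfg = SimulationConfig(K=3, p=20, N=450, d=1.5, seed=7)
    truth, X_groups = generate_study(cfg)
    return cfg, truth, X_groups
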