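import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_chipexo():
    """Compact simulated ChIP-exo study shared across tests."""
    from exoscreen.simulate import SimulationConfig, simulate_chipexo

    config = SimulationConfig(seed=11, n_genes=60, n_planted=8)
    return config, simulate_chipexo(config)
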