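import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ginitrend.synthetic_data import SyntheticConfig, generate_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_config():
    """A small but structurally complete generator config (3 regions, 8 waves)."""
    return SyntheticConfig(n_regions=3, units_per_region=12, noise_sd=0.005, seed=7)


@pytest.fixture
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture
def random_units(rng):
    """Factory for random (populations, providers) unit lists with providers > 0."""

    def make(n=None, max_units=50):
        while True:
            k = int(n or rng.integers(2, max_units + 1))
            pop = rng.lognormal(8.0, 1.0, k)
            prov = rng.poisson(pop * 0.002).astype(float)
            if prov.sum() > 0:
                return pop, prov

    return make
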