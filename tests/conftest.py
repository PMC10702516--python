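import numpy as np
import pytest

from greensar.synthetic_city import SyntheticCityConfig, generate_city, generate_points
from greensar.weights import build_kernel_weights


@pytest.fixture(scope="session")
def city400():
    """Small synthetic city with a strong, known greenspace effect."""
    cfg = SyntheticCityConfig(n_points=400, extent=(1500.0, 1500.0), rho_true=0.5,
                              beta_true=(0.0, -0.08, 0.05, -0.02, 0.08, 0.12),
                              seed=3)
    return generate_city(cfg)


@pytest.fixture(scope="session")
def points200():
    cfg = SyntheticCityConfig(n_points=200, extent=(1000.0, 1000.0), seed=11)
    return generate_points(cfg)


@pytest.fixture(scope="session")
def weights200(points200):
    return build_kernel_weights(points200, k=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
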