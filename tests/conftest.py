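import numpy as np
import pytest

from condpunish import GameParams


@pytest.fixture(scope="session")
def fig1_params() -> GameParams:
    """Benchmark well-mixed parameter set (r=3, c=1, G=5, alpha=1, beta=0.7, gamma=0.05, H=1)."""
    return GameParams(G=5, r=3.0, c=1.0, alpha=1.0, beta=0.7, gamma=0.05, H=1)


@pytest.fixture(scope="session")
def fig1_params_h3() -> GameParams:
    return GameParams(G=5, r=3.0, c=1.0, alpha=1.0, beta=0.7, gamma=0.05, H=3)


@pytest.fixture(scope="session")
def lattice_params() -> GameParams:
    """Benchmark lattice parameter set (r=2, alpha=1, beta=0.8, gamma=0.05)."""
    return GameParams(G=5, r=2.0, c=1.0, alpha=1.0, beta=0.8, gamma=0.05, H=1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
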