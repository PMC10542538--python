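import numpy as np
import pytest

from density_decode import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def binary_session():
    """Small, strongly modulated binary-choice session."""
    cfg = SimulationConfig(K=20, T=12, C=2, D=2, behavior_kind="binary",
                           base_rate=4.0, seed=11)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def continuous_session():
    """Small continuous-trace session (smooth GP behavior)."""
    cfg = SimulationConfig(K=20, T=12, C=3, D=2, behavior_kind="continuous",
                           base_rate=4.0, seed=12)
    return simulate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
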