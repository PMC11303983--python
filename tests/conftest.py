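import numpy as np
import pytest

from symtip import (
    ModelParameters,
    SimulationSettings,
    symmetric_default_parameters,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return symmetric_default_parameters()


@pytest.fixture(scope="session")
def fast_settings() -> SimulationSettings:
    """Shortened protocol for integration tests: 2e5 h per step with the
    convergence-gated early exit, which leaves recorded stable states within
    solver tolerance of the full-length protocol."""
    return SimulationSettings(step_duration=2e5, early_exit=True)


@pytest.fixture(scope="session")
def full_settings() -> SimulationSettings:
    """Full 1e6 h protocol with the convergence-gated early exit."""
    return SimulationSettings(early_exit=True)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240807)
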