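import numpy as np
import pytest

from conflictpipe.synth import AgentParams
from conflictpipe.task import SessionConfig


@pytest.fixture
def default_config() -> SessionConfig:
    return SessionConfig()


@pytest.fixture
def small_config() -> SessionConfig:
    """A short session for fast end-to-end runs."""
    return SessionConfig(n_trials=10, rng_seed=7)


@pytest.fixture
def reliable_agent() -> AgentParams:
    return AgentParams(p_success=1.0, p_omit=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
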