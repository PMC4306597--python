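import numpy as np
import pytest

from seqreg.sequence_sim import (
    AgentPolicy,
    ExperimentConfig,
    generate_session,
)


@pytest.fixture(scope="session")
def small_config() -> ExperimentConfig:
    """120-trial session: integral condition counts (60/30/30)."""
    return ExperimentConfig(n_trials=120)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, AgentPolicy(), seed=42)


@pytest.fixture(scope="session")
def default_session():
    """Full-size 1008-trial session with the default uniform agent."""
    return generate_session(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
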