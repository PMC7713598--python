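import numpy as np
import pytest

from cardsort.agent import AgentParams, run_agent
from cardsort.task import TaskConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_config():
    return TaskConfig(max_trials=20)


@pytest.fixture
def example_session():
    """A moderately noisy 128-trial simulated session."""
    return run_agent(AgentParams(lam=0.6, delta=0.35), seed=42)
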