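import numpy as np
import pytest

from dyadinfer.core import ModelConfig
from dyadinfer.simulate import SessionSpec, simulate_session


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def bot_session():
    """One seeded bot-pair session: (trial records, paired gaze streams)."""
    spec = SessionSpec(session_type="bot_pair", self_category="Kitchen", seed=11)
    return simulate_session(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
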