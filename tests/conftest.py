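import numpy as np
import pytest

from kicksense.datasets import scaled
from kicksense.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One default-config synthetic session (raw physical units)."""
    return generate_session(SynthConfig(seed=11, session_id="fix-default"))


@pytest.fixture(scope="session")
def scaled_session(default_session):
    return scaled(default_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
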