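import numpy as np
import pytest

from swayquest.quest import PsychometricModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def plain_model():
    """Weibull with no guess/lapse contamination (clean asymptotes)."""
    return PsychometricModel(beta=3.5, gamma=0.0, delta=0.0)


@pytest.fixture
def default_model():
    return PsychometricModel()
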