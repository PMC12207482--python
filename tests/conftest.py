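import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from partnerchoice import model

settings.register_profile(
    "ci",
    max_examples=100,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def focal_example() -> model.FocalParams:
    """The worked mid-parameter focal used by the hand-derived anchors."""
    return model.FocalParams(omega=0.5, s=0.5, b=0.5)


@pytest.fixture
def pop_example() -> model.PopulationParams:
    """Color-asymmetric population: 3/4 of purple and 1/4 of teal cooperate."""
    return model.PopulationParams(rho=0.75, tau=0.25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
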