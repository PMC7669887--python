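import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sharkstress.synthetic import Shark, StudyDesign

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def shark() -> Shark:
    """A 1-kg reference animal (mass correction is the identity)."""
    return Shark(
        id="ref_shark",
        mass=1.0,
        total_length=569.0,
        temperature=28.0,
        pco2=650.0,
        group_id="T28_C650_g1",
    )


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
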