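import numpy as np
import pytest

from popmatch import CongenerProfile, ScenarioConfig, generate_blanks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profile():
    return CongenerProfile(
        sample_id="s1",
        congeners=["2,3,7,8-TCDD", "PCB-126", "OCDD"],
        concentration=np.array([4.0, 2.0, 0.0]),
        teq=np.array([4.0, 0.2, 0.0]),
    )


@pytest.fixture
def scenario():
    return ScenarioConfig(seed=7)


@pytest.fixture
def blanks(scenario):
    return generate_blanks(scenario)


def random_normalized(rng, n=20):
    """A valid normalized pattern: values in [0,1] with the max forced to 1."""
    v = rng.uniform(0.0, 1.0, size=n)
    v[rng.integers(n)] = 1.0
    return v
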