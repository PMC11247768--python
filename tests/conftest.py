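import numpy as np
import pytest

import rarecohort as rc


@pytest.fixture(scope="session")
def profiles() -> dict[str, rc.DiseaseProfile]:
    return rc.builtin_profiles()


@pytest.fixture(scope="session")
def scd(profiles):
    return profiles["SCD"]


@pytest.fixture(scope="session")
def cf(profiles):
    return profiles["CF"]


@pytest.fixture(scope="session")
def dmd(profiles):
    return profiles["DMD"]


@pytest.fixture(scope="session")
def toy_table() -> rc.DemographicsTable:
    """Small deterministic frame: 2 states, 1000 people."""
    return rc.make_toy_demographics(2, 1000, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
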