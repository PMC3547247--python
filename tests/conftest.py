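import numpy as np
import pytest

from gcmotion.fields import ChemokineEnvironment
from gcmotion.scenarios import load_scenario, make_model


@pytest.fixture(scope="session")
def toy_scenario():
    return load_scenario("fig2_default")


@pytest.fixture(scope="session")
def full_scenario():
    return load_scenario("fig4_default")


@pytest.fixture(scope="session")
def toy_model(toy_scenario):
    return make_model("toy", toy_scenario.parameters)


@pytest.fixture(scope="session")
def full_model(full_scenario):
    return make_model("full", full_scenario.parameters)


@pytest.fixture(scope="session")
def unit_env():
    """Unit-width fields at -1.5 / +1.5 (the reduced-model geometry)."""
    return ChemokineEnvironment.symmetric(c=1.0, w=1.0, k=1.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
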