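import numpy as np
import pytest

from dermvbe import presets
from dermvbe.ivpt import IVPTDesign
from dermvbe.skin import SkinPhysiology
from dermvbe.systemic import Compound, SystemicModel


@pytest.fixture(scope="session")
def compound() -> Compound:
    return presets.desoximetasone()


@pytest.fixture(scope="session")
def spray():
    return presets.topicort_spray()


@pytest.fixture(scope="session")
def physiology() -> SkinPhysiology:
    # healthy volunteer, no vasoconstriction
    return presets.physiology_scenario("B")


@pytest.fixture(scope="session")
def design() -> IVPTDesign:
    return presets.ivpt_design()


@pytest.fixture(scope="session")
def systemic() -> SystemicModel:
    return presets.default_systemic()


@pytest.fixture(scope="session")
def dosing():
    return presets.default_dosing()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
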