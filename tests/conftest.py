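import numpy as np
import pytest

from protonct.materials import MATERIALS
from protonct.phantom import (
    PhantomModel,
    SphereBody,
    default_compensator,
    three_insert_phantom,
)
from protonct.transport import BeamSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    return three_insert_phantom()


@pytest.fixture(scope="session")
def plain_sphere():
    """75 mm PMMA sphere without inserts (for compensation checks)."""
    return PhantomModel(SphereBody(np.zeros(3), 75.0, MATERIALS["pmma"]))


@pytest.fixture(scope="session")
def water_sphere():
    return PhantomModel(SphereBody(np.zeros(3), 75.0, MATERIALS["water"]))


@pytest.fixture(scope="session")
def compensator():
    return default_compensator()


@pytest.fixture(scope="session")
def beam():
    return BeamSpec(energy=125.0, field_diameter=85.0)
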