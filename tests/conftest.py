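import numpy as np
import pytest

from amwspec import (AsymmetricRotor, DistortionSet, RotationalConstants,
                     datasets)


@pytest.fixture(scope="session")
def amp_0plus():
    """Parent monomer 0+ sublevel constants (global-fit values)."""
    rc, dist = datasets.state_constants("amp", "0plus")
    return rc, dist


@pytest.fixture(scope="session")
def amp_rotor(amp_0plus):
    rc, dist = amp_0plus
    return AsymmetricRotor(rc, dist)


@pytest.fixture(scope="session")
def amp_rigid_rotor(amp_0plus):
    rc, _ = amp_0plus
    return AsymmetricRotor(rc, DistortionSet())


@pytest.fixture(scope="session")
def amw_parent():
    rc, dist = datasets.state_constants("amw", "parent")
    return rc, dist


@pytest.fixture(scope="session")
def amp_fixture_geometry():
    return datasets.amp_geometry()


@pytest.fixture(scope="session")
def water_fixture_geometry():
    return datasets.water_geometry()
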