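"""Shared fixtures: synthetic sensor arrays, electrode poses and the
study-condition phantom case (all generated at test time)."""

import numpy as np
import pytest

from madopo.geometry import ElectrodeGeometry, ElectrodePose, make_helmet_array
from madopo.simulate import make_fixture_case, make_protocol_table1


@pytest.fixture(scope="session")
def helmet():
    """Full 102-magnetometer synthetic helmet."""
    return make_helmet_array(102, radius=120.0, coverage_deg=120.0, seed=0)


@pytest.fixture(scope="session")
def small_helmet():
    """Reduced 24-sensor helmet for cheap forward evaluations."""
    return make_helmet_array(24, radius=120.0, coverage_deg=120.0, seed=0)


@pytest.fixture(scope="session")
def geometry():
    return ElectrodeGeometry()


@pytest.fixture
def upright_pose():
    """Electrode at the origin pointing along +z, zero rotation."""
    return ElectrodePose(np.zeros(3), [0.0, 0.0, 1.0], 0.0)


@pytest.fixture(scope="session")
def protocol():
    return make_protocol_table1()


@pytest.fixture(scope="session")
def paper_case():
    """Study-condition synthetic phantom: 102 sensors, 24 measurements,
    electrode pose at the reference coordinates, rotation 99 degrees."""
    return make_fixture_case("paper-like", seed=0)


@pytest.fixture(scope="session")
def tiny_case():
    return make_fixture_case("tiny", seed=0)
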