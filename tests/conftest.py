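import numpy as np
import pytest
from hypothesis import settings

import vivolig as vl
from vivolig.contact import ContactEngine
from vivolig.kinematics import pose_to_transform

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def surfaces():
    return vl.make_implant_surfaces()


@pytest.fixture(scope="session")
def apparatus():
    return vl.make_ligament_set()


@pytest.fixture(scope="session")
def engine(surfaces):
    femoral, tibial = surfaces
    return ContactEngine(tibial, femoral)


@pytest.fixture(scope="session")
def reference_state(apparatus, engine):
    """Self-consistent 0-degree reference pose and calibrated apparatus."""
    pose, calibrated = vl.find_reference_state(apparatus, engine, vl.nominal_reference_pose())
    return pose, calibrated


@pytest.fixture(scope="session")
def compliance_curve():
    return vl.default_compliance_curve()


@pytest.fixture(scope="session")
def calibrated_apparatus(reference_state):
    return reference_state[1]


@pytest.fixture()
def nominal_transform():
    return pose_to_transform(vl.nominal_reference_pose())


@pytest.fixture(scope="session")
def exemplary_bundle():
    return vl.make_exemplary_lcl_fixture()
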