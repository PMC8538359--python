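import numpy as np
import pytest

from kneeplan.femur import DefectSpec, FemurSpec, apply_defect, generate_femur, preset_case
from kneeplan.spacer import SpacerParams


@pytest.fixture(scope="session")
def intact():
    """Default intact right femur fixture: (mesh, landmarks)."""
    return generate_femur(FemurSpec())


@pytest.fixture(scope="session")
def intact_mesh(intact):
    return intact[0]


@pytest.fixture(scope="session")
def intact_landmarks(intact):
    return intact[1]


def _case_fixture(name):
    spec, defect = preset_case(name)
    mesh, lm = generate_femur(spec)
    return apply_defect(mesh, lm, defect), lm, defect


@pytest.fixture(scope="session")
def case1():
    return _case_fixture("case1")


@pytest.fixture(scope="session")
def case2():
    return _case_fixture("case2")


@pytest.fixture(scope="session")
def case3():
    return _case_fixture("case3")


@pytest.fixture(scope="session")
def default_params():
    return SpacerParams()


@pytest.fixture(scope="session")
def fast_params():
    """Lower-resolution spacer for loops where speed matters."""
    return SpacerParams(resolution=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
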