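import numpy as np
import pytest

from vtmm import AxisSpec, build_uniform_tessellation


@pytest.fixture
def tess3():
    """Three unit cells with milestones at 1.0 and 2.0."""
    return build_uniform_tessellation(0.0, 1.0, 3)


@pytest.fixture
def tess20():
    """The scaled-down 20-cell grid over a 10-angstrom domain."""
    return build_uniform_tessellation(0.0, 0.5, 20)


@pytest.fixture
def axis_z():
    """Permeation axis along +z with the constriction at the origin."""
    return AxisSpec(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]), hcs_center=0.0)
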