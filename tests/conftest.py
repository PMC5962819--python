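import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eegunmix import (
    DEFAULT_HEAD,
    average_reference,
    default_alpha,
    project_to_directions,
    resolution_matrix,
    sloreta_operator,
    spherical_cortex_grid,
    standard_1020_montage,
    three_sphere_leadfield,
)


@pytest.fixture(scope="session")
def montage():
    return standard_1020_montage()


@pytest.fixture(scope="session")
def head():
    return DEFAULT_HEAD


@pytest.fixture(scope="session")
def grid200(head):
    return spherical_cortex_grid(200, 0.8, seed=1, head=head)


@pytest.fixture(scope="session")
def K_free(montage, head, grid200):
    """Average-referenced free-orientation lead field on the 200-voxel grid."""
    return average_reference(three_sphere_leadfield(montage, head, grid200))


@pytest.fixture(scope="session")
def K_fixed(K_free, grid200):
    return project_to_directions(K_free, grid200.normals)


@pytest.fixture(scope="session")
def sloreta_fixed(K_fixed):
    return sloreta_operator(K_fixed, default_alpha(K_fixed))


@pytest.fixture(scope="session")
def R_fixed(sloreta_fixed, K_fixed):
    return resolution_matrix(sloreta_fixed, K_fixed)


@pytest.fixture(scope="session")
def sloreta_free(K_free):
    return sloreta_operator(K_free, default_alpha(K_free))


@pytest.fixture(scope="session")
def R_free(sloreta_free, K_free):
    return resolution_matrix(sloreta_free, K_free)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
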