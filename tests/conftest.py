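import numpy as np
import pytest

from cyclobind import (
    CDBuildParams,
    build_cd,
    build_frame_basis,
    dopo_like_guest,
)


@pytest.fixture(scope="session")
def beta_cd():
    """Canonical-pose 7-unit host (base plane = XY, primary rim up)."""
    return build_cd(CDBuildParams(n_units=7, base_radius=5.0, tilt_deg=80.0))


@pytest.fixture(scope="session")
def beta_cd_basis(beta_cd):
    structure, topology = beta_cd
    return build_frame_basis(structure, topology)


@pytest.fixture(scope="session")
def guest():
    """Rigid three-ring guest template and its (tail, head) vector serials."""
    return dopo_like_guest()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    """Uniform random rotation matrix (for rigid-motion invariance tests)."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
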