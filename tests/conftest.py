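import numpy as np
import pytest
import trimesh

from aclrsim import fixtures as fx
from aclrsim import laxity_sim as lx
from aclrsim.surgery_planning import build_path, drill_tunnel


@pytest.fixture(scope="session")
def cylinder_mesh():
    return trimesh.creation.cylinder(radius=3.0, height=30.0, sections=64)


@pytest.fixture(scope="session")
def drilled_cube():
    """Cube with a through-tunnel: shared by drilling tests (slow to build)."""
    bone, landmarks = fx.make_block_bone(dims=(20.0, 20.0, 20.0))
    path = build_path(landmarks)
    drilled = drill_tunnel(bone, path, "tibial", radius=2.0)
    return {
        "bone": bone,
        "landmarks": landmarks,
        "path": path,
        "radius": 2.0,
        "drilled": drilled,
        "analytic_removed": np.pi * 2.0**2 * 20.0,
    }


@pytest.fixture()
def toy_knee():
    return fx.make_toy_knee()


@pytest.fixture(scope="session")
def rm_lachman():
    """Reference-model Lachman result (read-only)."""
    return lx.run_lachman(fx.make_toy_knee())


@pytest.fixture(scope="session")
def aclr_builder():
    def build(technique="SB", radius=4.0, material="semitendinosus"):
        return fx.make_toy_aclr(technique=technique, radius=radius, material=material)

    return build
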