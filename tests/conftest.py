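"""Shared fixtures: a bead phantom, the two-camera rig, and exact
bead projections at a known pose.  Everything is generated in memory."""

import numpy as np
import pytest

from bipreg.geometry import PointCloud, Pose, apply_rigid, project
from bipreg.synthetic import RigSpec, make_phantom, make_rig


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(n_surface_points=1500, n_beads=7, shape="femur", seed=1)


@pytest.fixture(scope="session")
def dense_phantom():
    return make_phantom(n_surface_points=4000, n_beads=7, shape="femur", seed=1)


@pytest.fixture(scope="session")
def rig():
    return make_rig(RigSpec())


@pytest.fixture(scope="session")
def beads(phantom):
    return phantom.bead_cloud()


@pytest.fixture(scope="session")
def true_pose():
    return Pose.from_degrees(3.0, -2.0, 5.0, 10.0, 20.0, -15.0)


@pytest.fixture(scope="session")
def master_exact(beads, rig, true_pose):
    """Noise-free bead projections at the true pose, one array per camera."""
    moved = apply_rigid(true_pose, beads)
    return [project(cam, moved) for cam in rig]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
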