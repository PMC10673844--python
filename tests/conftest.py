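"""Shared fixtures: toy assets, camera rings, and a hand-built 2-joint chain."""

import numpy as np
import pytest
import scipy.sparse as sp

from meshmocap.model_core import ArticulatedModel
from meshmocap.rig import (make_camera_ring, make_pose_library,
                           make_toy_model, scenario_preset)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def pose_library(toy_model):
    return make_pose_library(toy_model)


@pytest.fixture(scope="session")
def camera_ring():
    return make_camera_ring(10)


@pytest.fixture(scope="session")
def four_pigs():
    return scenario_preset("four_pigs_cage", seed=7)


def build_chain_model():
    """Two-joint chain: joint_0 at origin, joint_1 at (1,0,0), a vertex at
    (2,0,0) skinned fully to joint_1 — the hand-computable skinning case."""
    vertices = np.array([[2.0, 0.0, 0.0], [0.5, 0.0, 0.0],
                         [1.5, 0.2, 0.0]])
    faces = np.array([[0, 1, 2]])
    joints = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    skinning = sp.csr_matrix(np.array([[0.0, 1.0],
                                       [1.0, 0.0],
                                       [0.5, 0.5]]))
    regressor = sp.csr_matrix(np.array([[1.0, 0.0, 0.0]]))
    return ArticulatedModel(
        template_vertices=vertices, faces=faces, template_joints=joints,
        parent=np.array([-1, 0]), skinning_weights=skinning,
        keypoint_regressor=regressor, joint_part=["body", "body"],
        active_joints=np.array([0, 1]),
        joint_names=["root", "joint_1"], keypoint_names=["tip"])


@pytest.fixture
def chain_model():
    return build_chain_model()


def random_small_model(rng, n_joints=4, n_vertices=30):
    """Random valid kinematic chain for oracle comparisons."""
    joints = rng.normal(0, 0.3, (n_joints, 3))
    parent = np.array([-1] + [rng.integers(0, i) for i in range(1, n_joints)])
    vertices = rng.normal(0, 0.5, (n_vertices, 3))
    W = rng.random((n_vertices, n_joints)) ** 3
    W /= W.sum(axis=1, keepdims=True)
    R = rng.random((3, n_vertices))
    R /= R.sum(axis=1, keepdims=True)
    faces = np.array([[0, 1, 2]])
    return ArticulatedModel(
        template_vertices=vertices, faces=faces, template_joints=joints,
        parent=parent, skinning_weights=sp.csr_matrix(W),
        keypoint_regressor=sp.csr_matrix(R),
        joint_part=["body"] * n_joints,
        active_joints=np.arange(n_joints),
        joint_names=[f"j{i}" for i in range(n_joints)],
        keypoint_names=["a", "b", "c"])
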