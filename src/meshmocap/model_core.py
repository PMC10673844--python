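"""Articulated mesh model: linear blend skinning, keypoint regression, pose math.

The animal body is represented as a triangle mesh whose vertices are deformed
by an embedded kinematic skeleton.  Each joint carries a 3-DOF axis-angle
rotation; a sparse, row-stochastic skinning matrix blends the per-joint rigid
transforms into vertex positions, and a second sparse row-stochastic matrix
regresses named 3D keypoints (nose, ears, legs, ...) from the posed vertices.
On top of the skeletal pose sit four global parameters: an isotropic scale
``s``, a z-y-x Euler rotation ``r`` and a translation ``t``, so that posed
vertices are ``V = s * R(r) @ LBS(theta) + t``.

Conventions: units are meters, the world frame is z-up with the floor at
z = 0, and the global rotation is composed as ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``
(intrinsic z-y-x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ArticulatedModel",
    "PoseParams",
    "PosedSurface",
    "axis_angle_to_matrix",
    "euler_zyx_matrix",
    "load_model",
    "write_model",
    "lbs_pose",
    "lbs_keypoints",
    "normalize_pose",
    "downsample_vertices",
]

PART_NAMES = ("head", "body", "limb", "tail")
_ROW_SUM_TOL = 1e-8


class ModelValidationError(ValueError):
    """Raised when an articulated-model asset violates a structural invariant."""


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def axis_angle_to_matrix(phi: np.ndarray) -> np.ndarray:
    """Rodrigues' formula for a stack of axis-angle vectors.

    Parameters
    ----------
    phi : (..., 3) array
        Axis-angle vectors; the norm is the rotation angle in radians and a
        zero vector denotes the identity rotation.

    Returns
    -------
    (..., 3, 3) array of rotation matrices.
    """
    phi = np.asarray(phi, dtype=float)
    single = phi.ndim == 1
    phi = np.atleast_2d(phi)
    angle = np.linalg.norm(phi, axis=-1)
    out = np.broadcast_to(np.eye(3), phi.shape[:-1] + (3, 3)).copy()
    nz = angle > 0.0
    if np.any(nz):
        axis = phi[nz] / angle[nz, None]
        a = angle[nz]
        K = np.zeros((axis.shape[0], 3, 3))
        K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
        K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
        K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
        out[nz] = (
            np.eye(3)
            + np.sin(a)[:, None, None] * K
            + (1.0 - np.cos(a))[:, None, None] * (K @ K)
        )
    return out[0] if single else out


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_zyx_matrix(r: np.ndarray) -> np.ndarray:
    """Global rotation matrix from ``r = [r_z, r_y, r_x]``: ``Rz @ Ry @ Rx``."""
    rz, ry, rx = np.asarray(r, dtype=float)
    return _rot_z(rz) @ _rot_y(ry) @ _rot_x(rx)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ArticulatedModel:
    """Template mesh + skeleton + skinning/regression matrices.

    ``part_label`` assigns each vertex to one of :data:`PART_NAMES`; it is
    derived from the vertex's dominant skinning joint through the per-joint
    ``joint_part`` table when not supplied explicitly.
    """

    template_vertices: np.ndarray          # (N_V, 3) meters
    faces: np.ndarray                      # (N_F, 3) int
    template_joints: np.ndarray            # (N_J, 3) meters
    parent: np.ndarray                     # (N_J,) int, -1 for root
    skinning_weights: sp.csr_matrix        # (N_V, N_J) row-stochastic
    keypoint_regressor: sp.csr_matrix      # (N_K, N_V) row-stochastic
    joint_part: list[str] = field(default_factory=list)   # per joint
    active_joints: np.ndarray = field(default_factory=lambda: np.array([], int))
    joint_names: list[str] = field(default_factory=list)
    keypoint_names: list[str] = field(default_factory=list)
    part_label: np.ndarray | None = None   # (N_V,) str, derived if None

    def __post_init__(self):
        self.template_vertices = np.asarray(self.template_vertices, float)
        self.faces = np.asarray(self.faces, int)
        self.template_joints = np.asarray(self.template_joints, float)
        self.parent = np.asarray(self.parent, int)
        self.skinning_weights = sp.csr_matrix(self.skinning_weights)
        self.keypoint_regressor = sp.csr_matrix(self.keypoint_regressor)
        self.active_joints = np.asarray(self.active_joints, int)
        if self.part_label is None and self.joint_part:
            dom = np.asarray(self.skinning_weights.argmax(axis=1)).ravel()
            self.part_label = np.array([self.joint_part[j] for j in dom])
        self.validate()

    # sizes -----------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.template_vertices.shape[0]

    @property
    def n_joints(self) -> int:
        return self.template_joints.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.keypoint_regressor.shape[0]

    @property
    def n_active(self) -> int:
        return self.active_joints.size

    def validate(self) -> None:
        nv, nj = self.n_vertices, self.n_joints
        if self.skinning_weights.shape != (nv, nj):
            raise ModelValidationError(
                f"skinning shape {self.skinning_weights.shape} != ({nv},{nj})")
        if self.keypoint_regressor.shape[1] != nv:
            raise ModelValidationError("regressor column count != N_V")
        if self.skinning_weights.data.size and self.skinning_weights.data.min() < 0:
            raise ModelValidationError("negative skinning weight")
        row = np.asarray(self.skinning_weights.sum(axis=1)).ravel()
        bad = np.where(np.abs(row - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ModelValidationError(
                f"skinning row {bad[0]} sums to {row[bad[0]]:.6g}, expected 1")
        row = np.asarray(self.keypoint_regressor.sum(axis=1)).ravel()
        bad = np.where(np.abs(row - 1.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            raise ModelValidationError(
                f"regressor row {bad[0]} sums to {row[bad[0]]:.6g}, expected 1")
        if np.sum(self.parent < 0) != 1:
            raise ModelValidationError("parent array must have exactly one root")
        if np.any(self.parent >= np.arange(nj)):
            raise ModelValidationError(
                "parents must precede children (topologically sorted joints)")
        if self.active_joints.size and (
            self.active_joints.min() < 0 or self.active_joints.max() >= nj
        ):
            raise ModelValidationError("active joint index out of range")
        if self.part_label is not None:
            unknown = set(np.unique(self.part_label)) - set(PART_NAMES)
            if unknown:
                raise ModelValidationError(f"unknown part labels {unknown}")

    def head_vertex_indices(self) -> np.ndarray:
        return np.where(self.part_label == "head")[0]


@dataclass
class PoseParams:
    """Full pose: per-active-joint axis-angle stack plus global transform.

    The pose splits into a "local" part (joint rotations, height ``t_z`` and
    the ground-plane tilt ``r_x, r_y``) and a "global" part (``t_x, t_y``,
    heading ``r_z`` and scale ``s``); anchor-pose retrieval optimizes only the
    global part while inheriting the local part from the library entry.
    """

    theta: np.ndarray                      # (N_O, 3) axis-angle, active joints
    scale: float = 1.0
    global_rot: np.ndarray = field(default_factory=lambda: np.zeros(3))  # [rz,ry,rx]
    trans: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        self.global_rot = np.asarray(self.global_rot, float).copy()
        self.trans = np.asarray(self.trans, float).copy()
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def copy(self) -> "PoseParams":
        return PoseParams(self.theta.copy(), float(self.scale),
                          self.global_rot.copy(), self.trans.copy())

    def local_part(self) -> dict:
        """Θ^l = {θ, t_z, r_x, r_y}."""
        return {"theta": self.theta, "t_z": self.trans[2],
                "r_x": self.global_rot[2], "r_y": self.global_rot[1]}

    def global_part(self) -> dict:
        """Θ^g = {t_x, t_y, r_z, s}."""
        return {"t_x": self.trans[0], "t_y": self.trans[1],
                "r_z": self.global_rot[0], "s": self.scale}

    def local_vector(self) -> np.ndarray:
        """Flat Θ^l used by the anchor-pose prior distance."""
        return np.concatenate([self.theta.ravel(),
                               [self.trans[2], self.global_rot[2],
                                self.global_rot[1]]])


@dataclass
class PosedSurface:
    """Output of the skinning pass: posed vertices, joints and keypoints."""

    vertices: np.ndarray   # (N_V, 3)
    joints: np.ndarray     # (N_J, 3)
    keypoints: np.ndarray  # (N_K, 3)


# ---------------------------------------------------------------------------
# forward kinematics / skinning
# ---------------------------------------------------------------------------

def _joint_world_transforms(model: ArticulatedModel,
                            theta_full: np.ndarray) -> np.ndarray:
    """World-space 4x4 transforms G_i = G_parent @ T(J_i) Rot(phi_i) T(-J_i)."""
    nj = model.n_joints
    R = axis_angle_to_matrix(theta_full)
    G = np.empty((nj, 4, 4))
    for i in range(nj):
        local = np.eye(4)
        local[:3, :3] = R[i]
        J = model.template_joints[i]
        local[:3, 3] = J - R[i] @ J
        p = model.parent[i]
        G[i] = local if p < 0 else G[p] @ local
    return G


def _expand_theta(model: ArticulatedModel, pose: PoseParams) -> np.ndarray:
    theta_full = np.zeros((model.n_joints, 3))
    if pose.theta.shape != (model.n_active, 3):
        raise ValueError(
            f"theta shape {pose.theta.shape} != ({model.n_active}, 3)")
    theta_full[model.active_joints] = pose.theta
    return theta_full


def lbs_pose(model: ArticulatedModel, pose: PoseParams) -> PosedSurface:
    """Pose the full surface: skinning, then global scale/rotation/translation."""
    G = _joint_world_transforms(model, _expand_theta(model, pose))
    Vh = np.hstack([model.template_vertices,
                    np.ones((model.n_vertices, 1))])      # (N_V, 4)
    W = model.skinning_weights
    # accumulate w_vj * ((G_j - I) @ v) so the rest pose is exactly the
    # template even though skinning rows sum to 1 only in floating point
    D = G[:, :3, :].copy()
    D[:, :, :3] -= np.eye(3)
    DV = np.einsum("jab,vb->jva", D, Vh)                  # (N_J, N_V, 3)
    skinned = model.template_vertices.copy()
    coo = W.tocoo()
    np.add.at(skinned, coo.row, coo.data[:, None] * DV[coo.col, coo.row])
    joints = np.einsum("jab,jb->ja", G[:, :3, :],
                       np.hstack([model.template_joints,
                                  np.ones((model.n_joints, 1))]))
    Rg = euler_zyx_matrix(pose.global_rot)
    s = pose.scale
    vertices = s * skinned @ Rg.T + pose.trans
    joints = s * joints @ Rg.T + pose.trans
    keypoints = model.keypoint_regressor @ vertices
    return PosedSurface(vertices, joints, keypoints)


def _keypoint_support(model: ArticulatedModel):
    """Cached skinning data restricted to the keypoint-regressor support."""
    cache = getattr(model, "_kp_support", None)
    if cache is not None:
        return cache
    support = np.unique(model.keypoint_regressor.indices)
    coo = model.skinning_weights[support].tocoo()
    Vh = np.hstack([model.template_vertices[support],
                    np.ones((support.size, 1))])
    sub = model.keypoint_regressor[:, support].toarray()
    cache = (support, coo.row, coo.col, coo.data, Vh, sub)
    model._kp_support = cache
    return cache


def lbs_keypoints(model: ArticulatedModel, pose: PoseParams) -> np.ndarray:
    """Regressed 3D keypoints only, skinning just the regressor support.

    The keypoint regressor touches a few dozen vertices, so the fitting inner
    loop avoids posing the whole mesh.
    """
    support, row, col, data, Vh, sub = _keypoint_support(model)
    G = _joint_world_transforms(model, _expand_theta(model, pose))
    D = G[:, :3, :].copy()
    D[:, :, :3] -= np.eye(3)
    skinned = model.template_vertices[support].copy()
    contrib = np.einsum("nab,nb->na", D[col], Vh[row])
    np.add.at(skinned, row, data[:, None] * contrib)
    Rg = euler_zyx_matrix(pose.global_rot)
    verts = pose.scale * skinned @ Rg.T + pose.trans
    return sub @ verts


def normalize_pose(pose: PoseParams) -> PoseParams:
    """Remove the global part Θ^g: t_x = t_y = 0, r_z = 0, s = 1."""
    out = pose.copy()
    out.trans[0] = out.trans[1] = 0.0
    out.global_rot[0] = 0.0
    out.scale = 1.0
    return out


def downsample_vertices(model: ArticulatedModel, target_count: int) -> np.ndarray:
    """Deterministic, approximately uniform vertex subset.

    Farthest-point sampling on the template surface, seeded with vertex 0 and
    with the lowest-index vertex of every part present in the mesh, so that no
    body part disappears from the downsampled cloud.
    """
    nv = model.n_vertices
    if not 1 <= target_count <= nv:
        raise ValueError(f"target_count {target_count} not in [1, {nv}]")
    if target_count == nv:
        return np.arange(nv)
    V = model.template_vertices
    chosen = [0]
    if model.part_label is not None:
        for part in PART_NAMES:
            idx = np.where(model.part_label == part)[0]
            if idx.size and not any(model.part_label[c] == part for c in chosen):
                if len(chosen) < target_count:
                    chosen.append(int(idx[0]))
    selected = np.zeros(nv, dtype=bool)
    selected[chosen] = True
    dist = np.full(nv, np.inf)
    for c in chosen:
        dist = np.minimum(dist, np.linalg.norm(V - V[c], axis=1))
    while selected.sum() < target_count:
        cand = np.where(~selected)[0]
        # farthest unselected vertex; coincident duplicates fall back to
        # lowest index so the subset always reaches the requested size
        nxt = int(cand[np.argmax(dist[cand])])
        selected[nxt] = True
        dist = np.minimum(dist, np.linalg.norm(V - V[nxt], axis=1))
    return np.where(selected)[0]


# ---------------------------------------------------------------------------
# asset I/O  (OBJ mesh + skeleton JSON)
# ---------------------------------------------------------------------------

def _load_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        tok = line.split()
        if not tok or tok[0] not in ("v", "f"):
            continue
        try:
            if tok[0] == "v":
                verts.append([float(x) for x in tok[1:4]])
            else:
                faces.append([int(t.split("/")[0]) - 1 for t in tok[1:4]])
        except (ValueError, IndexError) as exc:
            raise ModelValidationError(
                f"{path}:{lineno}: malformed OBJ record {line!r}") from exc
    if not verts:
        raise ModelValidationError(f"{path}: no vertices found")
    return np.array(verts, float), np.array(faces, int).reshape(-1, 3)


def load_model(mesh_path, skeleton_path) -> ArticulatedModel:
    """Load an articulated model from a Wavefront OBJ + skeleton JSON pair."""
    mesh_path, skeleton_path = Path(mesh_path), Path(skeleton_path)
    verts, faces = _load_obj(mesh_path)
    sk = json.loads(skeleton_path.read_text())
    joints = np.array(sk["joints"], float)
    parents = np.array(sk["parents"], int)
    nj, nv = joints.shape[0], verts.shape[0]
    tri = np.array(sk["skinning"], float).reshape(-1, 3)
    skinning = sp.csr_matrix(
        (tri[:, 2], (tri[:, 0].astype(int), tri[:, 1].astype(int))),
        shape=(nv, nj))
    tri = np.array(sk["regressor"], float).reshape(-1, 3)
    nk = int(tri[:, 0].max()) + 1 if tri.size else 0
    regressor = sp.csr_matrix(
        (tri[:, 2], (tri[:, 0].astype(int), tri[:, 1].astype(int))),
        shape=(nk, nv))
    joint_names = sk.get("joint_names", [f"joint_{i}" for i in range(nj)])
    parts_table = sk.get("parts", {})
    joint_part = [parts_table.get(name, "body") for name in joint_names]
    return ArticulatedModel(
        template_vertices=verts, faces=faces, template_joints=joints,
        parent=parents, skinning_weights=skinning,
        keypoint_regressor=regressor, joint_part=joint_part,
        active_joints=np.array(sk.get("active", []), int),
        joint_names=joint_names,
        keypoint_names=sk.get("keypoint_names", []))


def write_model(model: ArticulatedModel, mesh_path, skeleton_path) -> None:
    """Write the OBJ + skeleton JSON pair; round-trips through load_model."""
    mesh_path, skeleton_path = Path(mesh_path), Path(skeleton_path)
    with open(mesh_path, "w") as fh:
        for v in model.template_vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in model.faces:
            fh.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")
    sw = model.skinning_weights.tocoo()
    rg = model.keypoint_regressor.tocoo()
    names = model.joint_names or [f"joint_{i}" for i in range(model.n_joints)]
    sk = {
        "schema_version": 1,
        "joints": model.template_joints.tolist(),
        "parents": model.parent.tolist(),
        "skinning": [[int(r), int(c), float(d)]
                     for r, c, d in zip(sw.row, sw.col, sw.data)],
        "regressor": [[int(r), int(c), float(d)]
                      for r, c, d in zip(rg.row, rg.col, rg.data)],
        "parts": {name: part for name, part in zip(names, model.joint_part)},
        "active": model.active_joints.tolist(),
        "joint_names": names,
        "keypoint_names": model.keypoint_names,
    }
    skeleton_path.write_text(json.dumps(sk))
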