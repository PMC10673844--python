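"""Synthetic multi-camera rig: procedural quadruped, scripted motion, detections.

Everything the real pipeline consumes — an articulated mesh asset, a ring of
calibrated cameras, and per-frame per-view detections (bounding boxes,
keypoints with visibility, silhouette masks) — can be generated here with
exact ground truth, emulating a cage filmed by ~10 inward-looking cameras.
The animal is a procedural quadruped (ellipsoid torso, two-segment legs,
neck + head, 8-joint tail) with nearest-bone skinning and 19 regressed
keypoints; scripted walks interpolate between library poses while following
a ground path.  Detection corruption (pixel noise, visibility dropout,
occlusion-driven dropout from the z-buffer, mask erosion, per-view identity
shuffling) emulates what imperfect detectors would hand the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import binary_erosion
from scipy.spatial.transform import Rotation, Slerp

from .association import FrameDetections, Instance
from .fitting import AnchorPoseLibrary, rasterize_depth
from .geometry import CameraModel, project
from .model_core import ArticulatedModel, PoseParams, lbs_keypoints, lbs_pose

__all__ = [
    "ToyModelParams",
    "NoiseSpec",
    "RigScenario",
    "make_toy_model",
    "make_pose_library",
    "make_camera_ring",
    "WalkScript",
    "simulate_sequence",
    "scenario_preset",
    "ARENA_CENTER",
]

ARENA_CENTER = np.array([0.0, 0.0, 0.3])


# ---------------------------------------------------------------------------
# procedural quadruped
# ---------------------------------------------------------------------------

@dataclass
class ToyModelParams:
    """Body proportions of the procedural quadruped (meters).

    Defaults give a nose-to-tail-root body length of about 0.7 m, matching a
    juvenile pig; 7 cm is then 10% of the body length.
    """

    body_length: float = 0.66       # center-to-nose + center-to-tail-root span
    body_radius: float = 0.13
    leg_length: float = 0.38
    leg_radius: float = 0.03
    head_radius: float = 0.09
    tail_segments: int = 8
    tail_segment_length: float = 0.035
    jitter: float = 0.0             # optional seeded vertex jitter


def _toy_skeleton(p: ToyModelParams):
    """Joint positions, parents, names and part labels, topologically sorted."""
    foot_z = 0.02
    shoulder_z = foot_z + p.leg_length
    elbow_z = foot_z + p.leg_length / 2.0
    cz = shoulder_z + 0.05                     # body center height
    hx = p.body_length / 2.0 * 0.42            # spine half-offset
    fx = p.body_length / 2.0 * 0.65            # nose-ward reach

    joints = []

    def J(name, pos, parent, part):
        joints.append((name, np.array(pos, float), parent, part))
        return len(joints) - 1

    c = J("center", (0, 0, cz), -1, "body")
    sf = J("spine_front", (hx, 0, cz), c, "body")
    nk = J("neck", (fx * 0.62, 0, cz + 0.04), sf, "head")
    hd = J("head", (fx * 0.80, 0, cz + 0.07), nk, "head")
    J("nose", (fx, 0, cz + 0.04), hd, "head")
    J("l_ear", (fx * 0.78, 0.05, cz + 0.12), hd, "head")
    J("r_ear", (fx * 0.78, -0.05, cz + 0.12), hd, "head")
    sr = J("spine_rear", (-hx, 0, cz), c, "body")
    for side, sy in (("l", 0.09), ("r", -0.09)):
        s = J(f"{side}_shoulder", (hx, sy, shoulder_z), sf, "limb")
        e = J(f"{side}_elbow", (hx, sy, elbow_z), s, "limb")
        J(f"{side}_front_paw", (hx, sy, foot_z), e, "limb")
    for side, sy in (("l", 0.09), ("r", -0.09)):
        h = J(f"{side}_hip", (-hx, sy, shoulder_z), sr, "limb")
        k = J(f"{side}_knee", (-hx, sy, elbow_z), h, "limb")
        J(f"{side}_hind_paw", (-hx, sy, foot_z), k, "limb")
    tx = -p.body_length / 2.0 * 0.70
    prev = sr
    for i in range(p.tail_segments):
        prev = J(f"tail_{i + 1}",
                 (tx - i * p.tail_segment_length, 0, cz + 0.02 - 0.012 * i),
                 prev, "tail")
    names = [j[0] for j in joints]
    pos = np.array([j[1] for j in joints])
    parents = np.array([j[2] for j in joints])
    parts = [j[3] for j in joints]
    return names, pos, parents, parts


def _icosphere(subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere (vertices, faces) via repeated edge subdivision."""
    t = (1 + np.sqrt(5)) / 2
    v = np.array([[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
                  [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
                  [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
                  [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
                  [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
                  [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])
    for _ in range(subdiv):
        verts = list(v)
        cache: dict[tuple, int] = {}

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts[a] + verts[b]
                m = m / np.linalg.norm(m)
                verts.append(m)
                cache[key] = len(verts) - 1
            return cache[key]

        nf = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            nf += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v, f = np.array(verts), np.array(nf)
    return v, f


def _tube(p0: np.ndarray, p1: np.ndarray, radius: float,
          n_sides: int = 6, n_rings: int = 3):
    """Open tube with end caps along a segment."""
    axis = p1 - p0
    length = np.linalg.norm(axis)
    axis = axis / max(length, 1e-12)
    ref = np.array([0, 0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0, 0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    verts, faces = [], []
    for r in range(n_rings):
        c = p0 + axis * (length * r / (n_rings - 1))
        for s in range(n_sides):
            a = 2 * np.pi * s / n_sides
            verts.append(c + radius * (np.cos(a) * u + np.sin(a) * w))
    for r in range(n_rings - 1):
        for s in range(n_sides):
            a = r * n_sides + s
            b = r * n_sides + (s + 1) % n_sides
            faces += [[a, b, a + n_sides], [b, b + n_sides, a + n_sides]]
    base = len(verts)
    verts += [p0, p1]
    for s in range(n_sides):
        b = (s + 1) % n_sides
        faces.append([base, s, b])
        top = (n_rings - 1) * n_sides
        faces.append([base + 1, top + b, top + s])
    return np.array(verts), np.array(faces)


def make_toy_model(params: ToyModelParams | None = None,
                   seed: int = 0,
                   active: str = "crucial") -> ArticulatedModel:
    """Build the procedural quadruped asset.

    ``active`` selects the optimizable joint set: "crucial" excludes the root
    and the terminal head features (nose, ears), leaving 24 joints with the
    default 8-segment tail; "all" activates every non-root joint.
    """
    p = params or ToyModelParams()
    names, jpos, parents, jparts = _toy_skeleton(p)
    nj = len(names)
    idx = {n: i for i, n in enumerate(names)}

    verts_list, faces_list = [], []

    def add(v, f):
        faces_list.append(f + sum(len(x) for x in verts_list))
        verts_list.append(v)

    sv, sf2 = _icosphere(2)
    torso = sv * np.array([p.body_length / 2.0 * 0.78, p.body_radius,
                           p.body_radius]) + jpos[idx["center"]]
    add(torso, sf2)
    sv1, sf1 = _icosphere(1)
    add(sv1 * p.head_radius + jpos[idx["head"]], sf1)
    add(sv1 * 0.035 + jpos[idx["nose"]], sf1)
    add(sv1 * 0.022 + jpos[idx["l_ear"]], sf1)
    add(sv1 * 0.022 + jpos[idx["r_ear"]], sf1)
    for side in ("l", "r"):
        for a, b in ((f"{side}_shoulder", f"{side}_elbow"),
                     (f"{side}_elbow", f"{side}_front_paw"),
                     (f"{side}_hip", f"{side}_knee"),
                     (f"{side}_knee", f"{side}_hind_paw")):
            v, f = _tube(jpos[idx[a]], jpos[idx[b]], p.leg_radius)
            add(v, f)
    for i in range(1, p.tail_segments):
        v, f = _tube(jpos[idx[f"tail_{i}"]], jpos[idx[f"tail_{i + 1}"]],
                     0.015, n_sides=5, n_rings=2)
        add(v, f)
    vertices = np.vstack(verts_list)
    faces = np.vstack(faces_list)
    if p.jitter > 0:
        rng = np.random.default_rng(seed)
        vertices = vertices + rng.normal(0, p.jitter, vertices.shape)

    # nearest-bone skinning with smooth falloff; bone (parent j -> child c)
    # contributes weight to the parent-side joint j
    bones = [(parents[i], i) for i in range(nj) if parents[i] >= 0]
    nb = len(bones)
    d = np.empty((vertices.shape[0], nb))
    bone_joint = np.empty(nb, dtype=int)
    for bi, (a, b) in enumerate(bones):
        bone_joint[bi] = a
        pa, pb = jpos[a], jpos[b]
        ab = pb - pa
        tproj = np.clip((vertices - pa) @ ab / max(ab @ ab, 1e-12), 0, 1)
        closest = pa + tproj[:, None] * ab
        d[:, bi] = np.linalg.norm(vertices - closest, axis=1)
    sigma = 0.04
    w_b = np.exp(-(d / sigma) ** 2)
    # keep the 3 nearest bones per vertex
    order = np.argsort(d, axis=1)
    keep = np.zeros_like(w_b, dtype=bool)
    np.put_along_axis(keep, order[:, :3], True, axis=1)
    w_b = np.where(keep, np.maximum(w_b, 1e-12), 0.0)
    W = np.zeros((vertices.shape[0], nj))
    for bi in range(nb):
        W[:, bone_joint[bi]] += w_b[:, bi]
    W /= W.sum(axis=1, keepdims=True)
    W[W < 1e-6] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    skinning = sp.csr_matrix(W)

    # keypoint regressor: average of the nearest template vertices to a target
    cz = jpos[idx["center"]][2]
    fx = p.body_length / 2.0 * 0.65
    kp_targets = {
        "nose": jpos[idx["nose"]],
        "l_eye": jpos[idx["head"]] + np.array([0.05, 0.045, 0.03]),
        "r_eye": jpos[idx["head"]] + np.array([0.05, -0.045, 0.03]),
        "l_ear": jpos[idx["l_ear"]],
        "r_ear": jpos[idx["r_ear"]],
        "l_shoulder": jpos[idx["l_shoulder"]],
        "r_shoulder": jpos[idx["r_shoulder"]],
        "l_elbow": jpos[idx["l_elbow"]],
        "r_elbow": jpos[idx["r_elbow"]],
        "l_front_paw": jpos[idx["l_front_paw"]],
        "r_front_paw": jpos[idx["r_front_paw"]],
        "l_hip": jpos[idx["l_hip"]],
        "r_hip": jpos[idx["r_hip"]],
        "l_knee": jpos[idx["l_knee"]],
        "r_knee": jpos[idx["r_knee"]],
        "l_hind_paw": jpos[idx["l_hind_paw"]],
        "r_hind_paw": jpos[idx["r_hind_paw"]],
        "tail_root": jpos[idx["tail_1"]],
        "center": jpos[idx["center"]],
    }
    kp_names = list(kp_targets)
    rows, cols, data = [], [], []
    for k, name in enumerate(kp_names):
        target = kp_targets[name]
        near = np.argsort(np.linalg.norm(vertices - target, axis=1))[:4]
        for vi in near:
            rows.append(k)
            cols.append(int(vi))
            data.append(0.25)
    regressor = sp.csr_matrix((data, (rows, cols)),
                              shape=(len(kp_names), vertices.shape[0]))

    if active == "all":
        active_joints = np.arange(1, nj)
    else:
        skip = {idx["center"], idx["nose"], idx["l_ear"], idx["r_ear"]}
        active_joints = np.array([i for i in range(nj) if i not in skip])
    return ArticulatedModel(
        template_vertices=vertices, faces=faces, template_joints=jpos,
        parent=parents, skinning_weights=skinning,
        keypoint_regressor=regressor, joint_part=jparts,
        active_joints=active_joints, joint_names=names,
        keypoint_names=kp_names)


# ---------------------------------------------------------------------------
# pose library
# ---------------------------------------------------------------------------

def _theta(model: ArticulatedModel, assignments: dict[str, np.ndarray]
           ) -> np.ndarray:
    th = np.zeros((model.n_active, 3))
    name_to_active = {model.joint_names[j]: i
                      for i, j in enumerate(model.active_joints)}
    for name, phi in assignments.items():
        th[name_to_active[name]] = phi
    return th


def make_pose_library(model: ArticulatedModel) -> AnchorPoseLibrary:
    """Small procedural anchor library: standing, lying (both sides), sitting,
    and a walking keyframe.  Every entry is normalized and floor-consistent."""
    z = np.zeros((model.n_active, 3))
    cz = model.template_joints[model.joint_names.index("center")][2]
    standing = PoseParams(z.copy())
    swing = 0.35
    walking = PoseParams(_theta(model, {
        "l_shoulder": [0, swing, 0], "r_hip": [0, swing, 0],
        "r_shoulder": [0, -swing, 0], "l_hip": [0, -swing, 0],
        "l_elbow": [0, -swing, 0], "r_knee": [0, -swing, 0]}))
    sitting = PoseParams(_theta(model, {
        "l_hip": [0, 1.1, 0], "r_hip": [0, 1.1, 0],
        "l_knee": [0, -1.3, 0], "r_knee": [0, -1.3, 0]}),
        global_rot=[0.0, -0.35, 0.0], trans=[0.0, 0.0, -0.04])
    lying_left = PoseParams(z.copy(), global_rot=[0.0, 0.0, np.pi / 2],
                            trans=[0.0, 0.0, 0.16 - cz])
    lying_right = PoseParams(z.copy(), global_rot=[0.0, 0.0, -np.pi / 2],
                             trans=[0.0, 0.0, 0.16 - cz])
    entries = [standing, walking, sitting, lying_left, lying_right]
    names = ["standing", "walking", "sitting", "lying_left", "lying_right"]
    # enforce the floor invariant exactly by lifting entries if needed
    fixed = []
    for e in entries:
        kp = lbs_keypoints(model, e)
        zmin = kp[:, 2].min()
        if zmin < 0:
            e = e.copy()
            e.trans[2] -= zmin
        fixed.append(e)
    return AnchorPoseLibrary.build(model, fixed, names)


# ---------------------------------------------------------------------------
# camera ring
# ---------------------------------------------------------------------------

def make_camera_ring(n: int = 10, radius: float = 2.2, height: float = 1.8,
                     image_size: tuple[int, int] = (1920, 1080),
                     target: np.ndarray = ARENA_CENTER) -> list[CameraModel]:
    """Evenly spaced inward-looking cameras on a ring (z-up, floor z = 0)."""
    if n < 2:
        raise ValueError("need at least 2 cameras")
    w, h = image_size
    K = np.array([[float(w), 0, w / 2.0],
                  [0, float(w), h / 2.0],
                  [0, 0, 1.0]])
    cams = []
    for i in range(n):
        a = 2 * np.pi * i / n
        C = np.array([radius * np.cos(a), radius * np.sin(a), height])
        fwd = target - C
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, np.array([0, 0, 1.0]))
        right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        R = np.vstack([right, down, fwd])
        t = -R @ C
        cams.append(CameraModel(K, R, t, np.zeros(5), (w, h)))
    return cams


# ---------------------------------------------------------------------------
# motion scripting
# ---------------------------------------------------------------------------

def interpolate_pose(a: PoseParams, b: PoseParams, u: float) -> PoseParams:
    """Per-joint slerp between two poses plus linear global interpolation."""
    th = np.empty_like(a.theta)
    for j in range(a.theta.shape[0]):
        key = Rotation.from_rotvec(np.vstack([a.theta[j], b.theta[j]]))
        th[j] = Slerp([0.0, 1.0], key)(u).as_rotvec()
    return PoseParams(th, (1 - u) * a.scale + u * b.scale,
                      (1 - u) * a.global_rot + u * b.global_rot,
                      (1 - u) * a.trans + u * b.trans)


@dataclass
class WalkScript:
    """Gait cycle between two library poses along a straight ground path."""

    start_xy: np.ndarray
    heading: float                   # r_z, radians
    speed: float = 0.3               # m/s
    gait_hz: float = 1.2             # keyframe oscillation frequency
    pose_a: PoseParams | None = None
    pose_b: PoseParams | None = None
    scale: float = 1.0

    def pose_at(self, t_sec: float, library: AnchorPoseLibrary) -> PoseParams:
        a = self.pose_a or library.entries[0]
        b = self.pose_b or library.entries[1]
        u = 0.5 * (1 - np.cos(2 * np.pi * self.gait_hz * t_sec))
        pose = interpolate_pose(a, b, float(u))
        direction = np.array([np.cos(self.heading), np.sin(self.heading)])
        xy = np.asarray(self.start_xy, float) + self.speed * t_sec * direction
        pose.trans = pose.trans + np.array([xy[0], xy[1], 0.0])
        pose.global_rot[0] = self.heading
        pose.scale = self.scale
        return pose


# ---------------------------------------------------------------------------
# scenario + simulation
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Detector-imperfection model applied to the exact projections."""

    keypoint_sigma: float = 2.0      # px Gaussian noise
    dropout_rate: float = 0.1        # random visibility dropout fraction
    occlusion_dropout: bool = False  # drop keypoints failing the depth test
    mask_erosion: int = 0            # px of binary erosion on masks
    identity_shuffle: bool = True    # randomize per-view instance order

    def __post_init__(self):
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass
class RigScenario:
    """A reproducible multi-animal capture setup."""

    model: ArticulatedModel
    cameras: list[CameraModel]
    library: AnchorPoseLibrary
    scripts: list[WalkScript]
    frame_rate: float = 25.0
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.scripts)


def scenario_preset(name: str, seed: int = 0,
                    image_size: tuple[int, int] = (1920, 1080)) -> RigScenario:
    """Built-in scenarios: "four_pigs_cage" (4 ids, 10 views), "two_dogs"
    (2 ids, 10 views), "single_mouse" (1 id, 6 views).  The presets share the
    same procedural quadruped; they mirror camera/identity counts only."""
    model = make_toy_model()
    library = make_pose_library(model)
    if name == "four_pigs_cage":
        cams = make_camera_ring(10, image_size=image_size)
        # four animals on a ring walking tangentially, >= 0.5 m apart
        scripts = []
        for i in range(4):
            a = np.pi / 2 * i + np.pi / 4
            start = 0.65 * np.array([np.cos(a), np.sin(a)])
            scripts.append(WalkScript(start, a + np.pi / 2, speed=0.25))
    elif name == "two_dogs":
        cams = make_camera_ring(10, image_size=image_size)
        scripts = [WalkScript(np.array([-0.5, -0.4]), 0.3, speed=0.3),
                   WalkScript(np.array([0.5, 0.4]), np.pi + 0.3, speed=0.3)]
    elif name == "single_mouse":
        cams = make_camera_ring(6, image_size=image_size)
        scripts = [WalkScript(np.array([-0.4, 0.0]), 0.0, speed=0.3)]
    else:
        raise ValueError(f"unknown preset {name!r}")
    return RigScenario(model, cams, library, scripts, seed=seed)


def simulate_sequence(scenario: RigScenario,
                      n_frames: int,
                      noise: NoiseSpec | None = None,
                      render_masks: bool = False,
                      mask_scale: float = 0.125) -> dict:
    """Generate ground truth and (optionally corrupted) detections.

    Returns a dict with keys ``poses`` (per frame per identity PoseParams),
    ``keypoints3d`` (per frame, (N_P, N_K, 3)), ``detections`` (per frame
    FrameDetections), ``identity_of`` (per frame per view: instance -> true
    identity), ``visibility`` (per frame (N_P, N_C, N_K) boolean, before
    random dropout).  Fully deterministic under the scenario seed.
    """
    noise = noise or NoiseSpec(keypoint_sigma=0.0, dropout_rate=0.0,
                               identity_shuffle=False)
    rng = np.random.default_rng(scenario.seed)
    model, cams = scenario.model, scenario.cameras
    n_p, n_c = scenario.n_individuals, len(cams)
    n_k = model.n_keypoints
    out = {"poses": [], "keypoints3d": [], "detections": [],
           "identity_of": [], "visibility": []}
    need_render = render_masks or noise.occlusion_dropout
    for f in range(n_frames):
        t = f / scenario.frame_rate
        poses = [s.pose_at(t, scenario.library) for s in scenario.scripts]
        surfaces = [lbs_pose(model, p) for p in poses]
        kp3d = np.stack([model.keypoint_regressor @ s.vertices
                         for s in surfaces])
        rendered = (rasterize_depth(cams, surfaces, model.faces, mask_scale)
                    if need_render else None)
        vis = np.ones((n_p, n_c, n_k), dtype=bool)
        frame = FrameDetections(mask_scale=mask_scale)
        identity_of = {}
        for c in range(n_c):
            insts = []
            ids = []
            for i in range(n_p):
                pix, valid, depth = project(cams[c], kp3d[i],
                                            return_valid=True)
                sigma = np.ones(n_k)
                sigma[~valid] = 0.0
                if rendered is not None:
                    view = rendered[c]
                    own, combined = view["own"][i], view["combined"]
                    h, w = own.shape
                    for m in range(n_k):
                        if sigma[m] == 0:
                            continue
                        col = int(round(pix[m, 0] * mask_scale))
                        row = int(round(pix[m, 1] * mask_scale))
                        if not (0 <= row < h and 0 <= col < w):
                            continue
                        if (np.isfinite(own[row, col])
                                and combined[row, col]
                                < own[row, col] - 0.01):
                            sigma[m] = 0.0
                vis[i, c] = sigma > 0
                if noise.occlusion_dropout:
                    pass  # depth-test dropout already applied above
                drop = rng.random(n_k) < noise.dropout_rate
                sigma[drop] = 0.0
                pts = pix + rng.normal(0, noise.keypoint_sigma, (n_k, 2)) \
                    if noise.keypoint_sigma > 0 else pix.copy()
                kp = np.column_stack([np.nan_to_num(pts, nan=-1.0), sigma])
                mask = None
                if render_masks:
                    mask = rendered[c]["silhouettes"][i]
                    if noise.mask_erosion > 0 and mask.any():
                        mask = binary_erosion(mask,
                                              iterations=noise.mask_erosion)
                visible_pts = pts[sigma > 0]
                if visible_pts.size:
                    x0, y0 = visible_pts.min(axis=0) - 10
                    x1, y1 = visible_pts.max(axis=0) + 10
                    bbox = [x0, y0, x1 - x0, y1 - y0]
                else:
                    bbox = [0, 0, 0, 0]
                insts.append(Instance(np.array(bbox), kp, mask))
                ids.append(i)
            if noise.identity_shuffle:
                order = rng.permutation(len(insts))
                insts = [insts[k] for k in order]
                ids = [ids[k] for k in order]
            frame.views[c] = insts
            identity_of[c] = {q: ids[q] for q in range(len(insts))}
        out["poses"].append(poses)
        out["keypoints3d"].append(kp3d)
        out["detections"].append(frame)
        out["identity_of"].append(identity_of)
        out["visibility"].append(vis)
    return out
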