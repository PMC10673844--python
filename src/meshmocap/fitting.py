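"""Energy-based articulated mesh fitting to multi-view 2D cues.

Per frame and per individual, the pose Θ (active-joint rotations, scale,
global rotation, translation) is found by damped least-squares minimization
of a weighted sum of energy terms:

* ``E_2D``     — squared pixel error between projected regressed keypoints and
  detected keypoints, confidence-weighted;
* ``E_sil``    — squared difference between the signed distance transforms of
  the rendered and the detected silhouettes, sampled at the projections of
  visible mesh vertices (visibility from per-individual vs. combined z-buffer
  depth maps);
* ``E_temp``   — squared displacement of keypoints relative to the previous
  frame (tracking only);
* ``E_reg``    — squared norm of the joint rotation stack;
* ``E_anchor`` — squared distance of the local pose to a retrieved library
  anchor pose plus a height prior on keypoint z (first frame only);
* ``E_floor``  — one-sided penalty pushing keypoints above the floor plane.

At the first frame the pose is initialized by anchor-pose retrieval: each
library entry keeps its local part Θ^l = {θ, t_z, r_x, r_y} fixed while the
global part Θ^g = {t_x, t_y, r_z, s} is fitted to the 2D keypoints; the entry
with the lowest combined keypoint + silhouette score wins.  At later frames
the previous frame's pose is inherited as initialization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .association import (FrameDetections, IdentityGrouping,
                          build_association_graph, partition_graph,
                          track_frame)
from .geometry import CameraModel, Observation2D, project, triangulate_mle
from .model_core import (ArticulatedModel, PoseParams, PosedSurface,
                         lbs_keypoints, lbs_pose)

logger = logging.getLogger("meshmocap")

__all__ = [
    "EnergyWeights",
    "FitSchedule",
    "AnchorPoseLibrary",
    "SDFImage",
    "FittedState",
    "sdf_from_mask",
    "rasterize_depth",
    "vertex_visibility",
    "filter_occluded_cues",
    "energy_2d",
    "energy_sil",
    "energy_priors",
    "retrieve_anchor_pose",
    "fit_frame",
    "fit_sequence",
    "baseline_triangulate",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EnergyWeights:
    """Term weights; defaults follow the published schedule.

    ``w_temp``/``w_anchor`` switch between initialization (w_temp=0,
    w_anchor=0.01) and tracking (w_temp=1, w_anchor=0).
    """

    w_2d: float = 1.0
    w_sil: float = 5e-5
    w_temp: float = 0.0
    w_reg: float = 0.01
    w_anchor: float = 0.01
    w_floor: float = 100.0
    lambda_h: float = 25.0
    retrieval_w_mask: float = 20.0
    w_3d: float = 0.0            # 1.0 enables the triangulated-keypoint term

    @classmethod
    def for_init(cls, **kw) -> "EnergyWeights":
        return cls(w_temp=0.0, w_anchor=0.01, **kw)

    @classmethod
    def for_tracking(cls, **kw) -> "EnergyWeights":
        return cls(w_temp=1.0, w_anchor=0.0, **kw)


@dataclass
class FitSchedule:
    """Iteration caps and LM damping schedule."""

    max_iter_init: int = 60
    max_iter_track: int = 5          # up to 15; 5 suffices in practice
    sil_warmup: int = 5              # w_sil forced to 0 for the first 5 iters
    render_every: int = 5            # refresh renders every k accepted steps
    lm_lambda0: float = 1e-3
    lm_up: float = 10.0
    lm_down: float = 0.5
    rel_tol: float = 1e-6
    scale_bounds: tuple[float, float] = (0.5, 2.0)
    raster_scale: float = 0.125      # working resolution for depth/SDF maps
    delta_z: float = 0.01            # visibility depth tolerance, meters
    rho_occ: float = 0.5             # silhouette occlusion-drop fraction


@dataclass
class AnchorPoseLibrary:
    """Predefined poses used as retrieval anchors at the first frame.

    Entries are stored normalized (t_x = t_y = 0, r_z = 0, s = 1) so that the
    local part carries only {θ, t_z, r_x, r_y}.  Every entry must satisfy the
    floor constraint: all cached keypoints at z >= 0.
    """

    entries: list[PoseParams]
    keypoints: list[np.ndarray] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    @classmethod
    def build(cls, model: ArticulatedModel, entries: list[PoseParams],
              names: list[str] | None = None) -> "AnchorPoseLibrary":
        kps = [lbs_keypoints(model, p) for p in entries]
        for i, kp in enumerate(kps):
            if kp[:, 2].min() < -1e-9:
                raise ValueError(
                    f"library entry {i} violates the floor constraint")
        return cls(entries, kps, names or [f"pose_{i}"
                                           for i in range(len(entries))])


@dataclass
class SDFImage:
    """Normalized signed distance image: negative inside, zero on boundary."""

    values: np.ndarray
    provenance: str = "detected"      # "detected" | "rendered"


@dataclass
class FittedState:
    """Per-individual per-frame fitting output."""

    frame: int
    identity: int
    pose: PoseParams
    keypoints: np.ndarray             # (N_K, 3) meters
    n_views_seen: np.ndarray          # (N_K,) int
    broken: bool = False
    energy_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# silhouettes, depth maps, visibility
# ---------------------------------------------------------------------------

def sdf_from_mask(mask: np.ndarray) -> SDFImage:
    """Signed Euclidean distance transform of a binary silhouette.

    Negative inside the foreground, positive outside, normalized by half the
    image diagonal and clipped to [-1, 1].
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty silhouette mask")
    outside = distance_transform_edt(~mask)
    inside = distance_transform_edt(mask)
    sdf = outside - inside
    half_diag = 0.5 * float(np.hypot(*mask.shape))
    return SDFImage(np.clip(sdf / half_diag, -1.0, 1.0))


def rasterize_mesh(camera: CameraModel, vertices: np.ndarray,
                   faces: np.ndarray) -> np.ndarray:
    """Software z-buffer: returns a (H, W) depth map (inf = background)."""
    w, h = camera.image_size
    depth_img = np.full((h, w), np.inf)
    pix, valid, depth = project(camera, vertices, return_valid=True)
    n_degenerate = 0
    for f in faces:
        if not np.all(valid[f]):
            continue
        p = pix[f]                                   # (3, 2)
        x0, y0 = np.floor(p.min(axis=0)).astype(int)
        x1, y1 = np.ceil(p.max(axis=0)).astype(int)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1 + 1, w), min(y1 + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        det = ((p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
               - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1]))
        if abs(det) < 1e-12:
            n_degenerate += 1
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1) + 0.5,
                             np.arange(y0, y1) + 0.5)
        b1 = ((gx - p[0, 0]) * (p[2, 1] - p[0, 1])
              - (p[2, 0] - p[0, 0]) * (gy - p[0, 1])) / det
        b2 = ((p[1, 0] - p[0, 0]) * (gy - p[0, 1])
              - (gx - p[0, 0]) * (p[1, 1] - p[0, 1])) / det
        b0 = 1.0 - b1 - b2
        inside = (b0 >= 0) & (b1 >= 0) & (b2 >= 0)
        if not inside.any():
            continue
        z = b0 * depth[f[0]] + b1 * depth[f[1]] + b2 * depth[f[2]]
        tile = depth_img[y0:y1, x0:x1]
        upd = inside & (z < tile)
        tile[upd] = z[upd]
    return depth_img


def rasterize_depth(cameras: list[CameraModel],
                    surfaces: list[PosedSurface],
                    faces: np.ndarray,
                    scale: float = 1.0) -> list[dict]:
    """Render every individual into every view at a working resolution.

    Returns one dict per view with keys ``own`` (list of per-individual depth
    maps), ``combined`` (per-pixel minimum over individuals) and
    ``silhouettes`` (list of per-individual boolean masks).
    """
    out = []
    for cam in cameras:
        wcam = cam.scaled(scale) if scale != 1.0 else cam
        w, h = wcam.image_size
        own = [rasterize_mesh(wcam, s.vertices, faces) for s in surfaces]
        combined = (np.minimum.reduce(own) if own
                    else np.full((h, w), np.inf))
        sils = [np.isfinite(d) for d in own]
        out.append({"own": own, "combined": combined, "silhouettes": sils,
                    "camera": wcam})
    return out


def vertex_visibility(own_depth: np.ndarray, combined_depth: np.ndarray,
                      projected: np.ndarray, depths: np.ndarray,
                      delta_z: float = 0.01) -> np.ndarray:
    """Indices of vertices whose own depth wins the combined z-buffer.

    A vertex is visible when the combined depth at its projected pixel is not
    closer than the vertex itself by more than ``delta_z`` (so vertices on the
    visible surface pass and vertices behind another body fail).
    """
    h, w = own_depth.shape
    idx = []
    cols = np.round(projected[:, 0]).astype(int)
    rows = np.round(projected[:, 1]).astype(int)
    for q in range(projected.shape[0]):
        r, c = rows[q], cols[q]
        if not (0 <= r < h and 0 <= c < w) or not np.isfinite(depths[q]):
            continue
        if combined_depth[r, c] >= depths[q] - delta_z:
            idx.append(q)
    return np.array(idx, dtype=int)


def filter_occluded_cues(grouping: IdentityGrouping,
                         rendered: list[dict],
                         frame: FrameDetections,
                         rho_occ: float = 0.5,
                         delta_z: float = 0.01,
                         det_scale: float = 1.0,
                         log: list | None = None) -> FrameDetections:
    """Drop keypoints and silhouettes contradicted by the occlusion state.

    ``rendered`` is the output of :func:`rasterize_depth` for the previous
    fitted state with per-individual depth maps in identity order.  A detected
    keypoint of identity ``i`` is dropped (σ → 0) when another individual's
    surface is in front of identity ``i`` at that pixel; a silhouette is
    dropped when more than ``rho_occ`` of its rendered area is covered by
    closer individuals.  ``det_scale`` converts detection pixel coordinates to
    the rendered working resolution.
    """
    import copy
    cleaned = copy.deepcopy(frame)
    for ident, group in enumerate(grouping.groups):
        for (c, q) in group:
            view = rendered[c]
            own = view["own"][ident]
            combined = view["combined"]
            s = det_scale
            inst = cleaned.views[c][q]
            h, w = own.shape
            kps = inst.keypoints
            for m in range(kps.shape[0]):
                if kps[m, 2] <= 0:
                    continue
                col = int(round(kps[m, 0] * s))
                row = int(round(kps[m, 1] * s))
                if not (0 <= row < h and 0 <= col < w):
                    continue
                if (np.isfinite(own[row, col])
                        and combined[row, col] < own[row, col] - delta_z):
                    kps[m, 2] = 0.0
                    if log is not None:
                        log.append({"kind": "keypoint", "view": c,
                                    "instance": q, "keypoint": m,
                                    "identity": ident})
            sil_own = view["silhouettes"][ident]
            occluded = sil_own & (combined < own - delta_z)
            area = sil_own.sum()
            if area and occluded.sum() / area > rho_occ:
                inst.mask = None
                if log is not None:
                    log.append({"kind": "silhouette", "view": c,
                                "instance": q, "identity": ident})
    return cleaned


def _sample_bilinear(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sampling at (x, y) pixel positions, clamped to the image."""
    h, w = img.shape
    x = np.clip(pts[:, 0], 0, w - 1.001)
    y = np.clip(pts[:, 1], 0, h - 1.001)
    x0, y0 = np.floor(x).astype(int), np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    v00 = img[y0, x0]
    v01 = img[y0, x0 + 1]
    v10 = img[y0 + 1, x0]
    v11 = img[y0 + 1, x0 + 1]
    return (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
            + v10 * (1 - fx) * fy + v11 * fx * fy)


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------

def energy_2d(model: ArticulatedModel, pose: PoseParams,
              cues: dict[int, np.ndarray],
              cameras: list[CameraModel]) -> float:
    """Σ_c Σ_m σ_m^c ||π^c(X_m(Θ)) − y_m^c||²; invisible keypoints contribute 0."""
    X = lbs_keypoints(model, pose)
    total = 0.0
    for c, y in cues.items():
        vis = y[:, 2] > 0
        if not np.any(vis):
            continue
        pix = project(cameras[c], X[vis])
        d2 = np.sum((pix - y[vis, :2]) ** 2, axis=1)
        d2 = np.where(np.isfinite(d2), d2, 1e12)
        total += float(np.sum(y[vis, 2] * d2))
    return total


def energy_sil(model: ArticulatedModel, pose: PoseParams,
               detected_sdfs: dict[int, SDFImage],
               rendered: list[dict], identity: int,
               cameras: list[CameraModel],
               exclude_tail: bool = False,
               delta_z: float = 0.01) -> float:
    """Squared rendered-vs-detected SDF difference at visible vertex projections."""
    surf = lbs_pose(model, pose)
    total = 0.0
    keep = None
    if exclude_tail and model.part_label is not None:
        keep = model.part_label != "tail"
    for c, sdf_d in detected_sdfs.items():
        view = rendered[c]
        wcam = view["camera"]
        own = view["own"][identity]
        sdf_p = sdf_from_mask(view["silhouettes"][identity]).values \
            if view["silhouettes"][identity].any() else None
        if sdf_p is None:
            continue
        pix, valid, depth = project(wcam, surf.vertices, return_valid=True)
        vis = vertex_visibility(own, view["combined"], pix, depth, delta_z)
        if keep is not None:
            vis = vis[keep[vis]]
        if vis.size == 0:
            continue
        diff = (_sample_bilinear(sdf_p, pix[vis])
                - _sample_bilinear(sdf_d.values, pix[vis]))
        total += float(np.sum(diff ** 2))
    return total


def _ramp(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def energy_priors(pose: PoseParams, prev_pose: PoseParams | None,
                  anchor: PoseParams | None,
                  model: ArticulatedModel,
                  weights: EnergyWeights) -> dict[str, float]:
    """E_temp, E_reg, E_anchor, E_floor for the current pose."""
    X = lbs_keypoints(model, pose)
    out = {"E_reg": float(np.sum(pose.theta ** 2)),
           "E_floor": float(np.sum(_ramp(-X[:, 2]) ** 2))}
    if weights.w_temp > 0:
        if prev_pose is None:
            raise ValueError("E_temp requires the previous pose")
        Xp = lbs_keypoints(model, prev_pose)
        out["E_temp"] = float(np.sum((X - Xp) ** 2))
    else:
        out["E_temp"] = 0.0
    if weights.w_anchor > 0:
        if anchor is None:
            raise ValueError("E_anchor requires an anchor pose")
        Xa = lbs_keypoints(model, anchor)
        dl = pose.local_vector() - anchor.local_vector()
        out["E_anchor"] = float(np.sum(dl ** 2)
                                + weights.lambda_h
                                * np.sum((X[:, 2] - Xa[:, 2]) ** 2))
    else:
        out["E_anchor"] = 0.0
    return out


# ---------------------------------------------------------------------------
# damped least squares (Levenberg-Marquardt)
# ---------------------------------------------------------------------------

def _lm_minimize(residual_fn, p0: np.ndarray, max_iter: int,
                 schedule: FitSchedule):
    """Generic damped LM with forward-difference Jacobian.

    Accepted steps never increase the objective; returns (p, energies) where
    ``energies`` lists the objective after every accepted step.
    """
    p = p0.copy()
    r = residual_fn(p)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("non-finite residuals at the initial pose")
    energy = float(r @ r)
    energies = [energy]
    lam = schedule.lm_lambda0
    n = p.size
    eps = 1e-6
    for _ in range(max_iter):
        J = np.empty((r.size, n))
        for j in range(n):
            dp = p.copy()
            dp[j] += eps
            J[:, j] = (residual_fn(dp) - r) / eps
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _try in range(8):
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(
                    np.maximum(np.diag(JtJ), 1e-12)), -g)
            except np.linalg.LinAlgError:
                lam *= schedule.lm_up
                continue
            p_new = p + delta
            r_new = residual_fn(p_new)
            if not np.all(np.isfinite(r_new)):
                lam *= schedule.lm_up
                continue
            e_new = float(r_new @ r_new)
            if e_new <= energy:
                rel = (energy - e_new) / max(energy, 1e-30)
                p, r, energy = p_new, r_new, e_new
                energies.append(energy)
                lam = max(lam * schedule.lm_down, 1e-12)
                accepted = True
                if rel < schedule.rel_tol:
                    return p, energies
                break
            lam *= schedule.lm_up
        if not accepted:
            return p, energies
    return p, energies


def _pack(pose: PoseParams) -> np.ndarray:
    return np.concatenate([pose.theta.ravel(), [pose.scale],
                           pose.global_rot, pose.trans])


def _unpack(p: np.ndarray, n_active: int,
            schedule: FitSchedule) -> PoseParams:
    nt = n_active * 3
    s = float(np.clip(p[nt], *schedule.scale_bounds))
    return PoseParams(p[:nt].reshape(n_active, 3), s,
                      p[nt + 1:nt + 4], p[nt + 4:nt + 7])


# ---------------------------------------------------------------------------
# anchor-pose retrieval
# ---------------------------------------------------------------------------

def _fit_global_transform(model: ArticulatedModel, entry: PoseParams,
                          cues: dict[int, np.ndarray],
                          cameras: list[CameraModel],
                          schedule: FitSchedule) -> PoseParams:
    """Optimize Θ^g = {t_x, t_y, r_z, s} of a library entry against E_2D."""
    # coarse translation init from DLT triangulation of visible keypoints
    pts = []
    n_k = model.n_keypoints
    for m in range(n_k):
        obs = [Observation2D(c, y[m, :2], y[m, 2])
               for c, y in cues.items() if y[m, 2] > 0]
        if len({o.view for o in obs}) >= 2:
            from .geometry import triangulate_dlt
            X = triangulate_dlt(obs, cameras)
            if X is not None and np.all(np.abs(X) < 50):
                pts.append(X)
    center0 = np.mean(pts, axis=0) if pts else np.zeros(3)

    def residual(p):
        pose = entry.copy()
        pose.trans[0], pose.trans[1] = p[0], p[1]
        pose.global_rot[0] = p[2]
        pose.scale = float(np.clip(p[3], *schedule.scale_bounds))
        X = lbs_keypoints(model, pose)
        res = []
        for c, y in cues.items():
            vis = y[:, 2] > 0
            if not np.any(vis):
                continue
            pix = project(cameras[c], X[vis])
            r = ((pix - y[vis, :2])
                 * np.sqrt(y[vis, 2])[:, None]).ravel()
            r[~np.isfinite(r)] = 1e4
            res.append(r)
        return np.concatenate(res) if res else np.zeros(1)

    best = None
    for rz0 in np.linspace(0, 2 * np.pi, 8, endpoint=False):
        p0 = np.array([center0[0], center0[1], rz0, 1.0])
        p, energies = _lm_minimize(residual, p0, 20, schedule)
        if best is None or energies[-1] < best[1]:
            best = (p, energies[-1])
    p = best[0]
    fitted = entry.copy()
    fitted.trans[0], fitted.trans[1] = p[0], p[1]
    fitted.global_rot[0] = p[2]
    fitted.scale = float(np.clip(p[3], *schedule.scale_bounds))
    return fitted


def retrieve_anchor_pose(library: AnchorPoseLibrary,
                         cues: dict[int, np.ndarray],
                         cameras: list[CameraModel],
                         model: ArticulatedModel,
                         detected_sdfs: dict[int, SDFImage] | None = None,
                         sdf_cameras: list[CameraModel] | None = None,
                         weights: EnergyWeights | None = None,
                         schedule: FitSchedule | None = None):
    """Select the library pose explaining the cues best.

    For each entry only the global transform is optimized against the
    keypoint term; entries are then scored with keypoint error plus (when
    silhouettes are available) a Chamfer-style silhouette term with weight
    ``retrieval_w_mask``, tail vertices ignored.  Returns
    ``(index, fitted_pose, score)``.
    """
    if not library.entries:
        raise ValueError("empty anchor pose library")
    weights = weights or EnergyWeights.for_init()
    schedule = schedule or FitSchedule()
    keep = None
    if model.part_label is not None:
        keep = np.where(model.part_label != "tail")[0]
    best = None
    for p_idx, entry in enumerate(library.entries):
        fitted = _fit_global_transform(model, entry, cues, cameras, schedule)
        score = energy_2d(model, fitted, cues, cameras)
        if detected_sdfs:
            surf = lbs_pose(model, fitted)
            verts = surf.vertices if keep is None else surf.vertices[keep]
            for c, sdf_d in detected_sdfs.items():
                cam = (sdf_cameras or cameras)[c]
                pix, valid, _ = project(cam, verts, return_valid=True)
                if not valid.any():
                    continue
                d = _sample_bilinear(sdf_d.values, pix[valid])
                score += weights.retrieval_w_mask * float(np.mean(d ** 2))
        if best is None or score < best[2]:
            best = (p_idx, fitted, score)
    return best


# ---------------------------------------------------------------------------
# per-frame fitting
# ---------------------------------------------------------------------------

def fit_frame(model: ArticulatedModel,
              init_pose: PoseParams,
              cues: dict[int, np.ndarray],
              cameras: list[CameraModel],
              weights: EnergyWeights | None = None,
              schedule: FitSchedule | None = None,
              mode: str = "init",
              prev_pose: PoseParams | None = None,
              anchor: PoseParams | None = None,
              detected_sdfs: dict[int, SDFImage] | None = None,
              other_surfaces: list[PosedSurface] | None = None,
              sdf_scale: float = 1.0,
              target_keypoints3d: np.ndarray | None = None):
    """Minimize the total energy for one individual in one frame.

    Returns ``(pose, trace)`` where ``trace`` is the list of per-render-cycle
    accepted-step energy sequences (each non-increasing).  The silhouette term
    is disabled for the first ``sil_warmup`` iterations and whenever no
    detected silhouette is available.  When ``weights.w_3d > 0`` and
    ``target_keypoints3d`` is given (typically MLE-triangulated keypoints,
    NaN where untriangulatable), an extra term penalizes the squared distance
    between regressed and target keypoints — the tail-tracking workflow.
    """
    weights = weights or (EnergyWeights.for_init() if mode == "init"
                          else EnergyWeights.for_tracking())
    schedule = schedule or FitSchedule()
    n_active = model.n_active
    max_iter = (schedule.max_iter_init if mode == "init"
                else schedule.max_iter_track)
    Xa = lbs_keypoints(model, anchor) if (anchor is not None
                                          and weights.w_anchor > 0) else None
    Xp = lbs_keypoints(model, prev_pose) if (prev_pose is not None
                                             and weights.w_temp > 0) else None
    if weights.w_temp > 0 and Xp is None:
        raise ValueError("E_temp requires prev_pose")
    if weights.w_anchor > 0 and Xa is None:
        raise ValueError("E_anchor requires anchor")
    X3d_mask = None
    if weights.w_3d > 0:
        if target_keypoints3d is None:
            raise ValueError("E_3D requires target_keypoints3d")
        X3d_mask = np.isfinite(target_keypoints3d).all(axis=1)

    def residual_keypoint(p, frozen_sil=None):
        pose = _unpack(p, n_active, schedule)
        X = lbs_keypoints(model, pose)
        res = []
        if weights.w_2d > 0:
            for c, y in cues.items():
                vis = y[:, 2] > 0
                if not np.any(vis):
                    continue
                pix = project(cameras[c], X[vis])
                r = ((pix - y[vis, :2])
                     * np.sqrt(weights.w_2d * y[vis, 2])[:, None]).ravel()
                r[~np.isfinite(r)] = 1e4
                res.append(r)
        if Xp is not None:
            res.append(np.sqrt(weights.w_temp) * (X - Xp).ravel())
        if X3d_mask is not None and X3d_mask.any():
            res.append(np.sqrt(weights.w_3d)
                       * (X[X3d_mask]
                          - target_keypoints3d[X3d_mask]).ravel())
        if weights.w_reg > 0:
            res.append(np.sqrt(weights.w_reg) * p[:n_active * 3])
        if Xa is not None:
            dl = pose.local_vector() - anchor.local_vector()
            res.append(np.sqrt(weights.w_anchor) * dl)
            res.append(np.sqrt(weights.w_anchor * weights.lambda_h)
                       * (X[:, 2] - Xa[:, 2]))
        if weights.w_floor > 0:
            res.append(np.sqrt(weights.w_floor) * _ramp(-X[:, 2]))
        if frozen_sil is not None:
            surf_v = lbs_pose(model, pose).vertices
            for c, (sdf_p, sdf_d, vis_idx, wcam) in frozen_sil.items():
                if vis_idx.size == 0:
                    continue
                pix = project(wcam, surf_v[vis_idx])
                pix = np.nan_to_num(pix, nan=0.0)
                diff = (_sample_bilinear(sdf_p, pix)
                        - _sample_bilinear(sdf_d.values, pix))
                res.append(np.sqrt(weights.w_sil) * diff)
        return np.concatenate(res) if res else np.zeros(1)

    p = _pack(init_pose)
    trace = []
    use_sil = bool(detected_sdfs) and weights.w_sil > 0
    warmup = min(schedule.sil_warmup, max_iter)
    p, energies = _lm_minimize(residual_keypoint, p, warmup if use_sil
                               else max_iter, schedule)
    trace.append(energies)
    if use_sil:
        done = warmup
        while done < max_iter:
            pose = _unpack(p, n_active, schedule)
            surfaces = [lbs_pose(model, pose)] + list(other_surfaces or [])
            rendered = rasterize_depth(cameras, surfaces, model.faces,
                                       sdf_scale)
            frozen = {}
            for c, sdf_d in detected_sdfs.items():
                view = rendered[c]
                sil = view["silhouettes"][0]
                if not sil.any():
                    continue
                sdf_p = sdf_from_mask(sil).values
                pix, valid, depth = project(view["camera"],
                                            surfaces[0].vertices,
                                            return_valid=True)
                vis = vertex_visibility(view["own"][0], view["combined"],
                                        pix, depth, schedule.delta_z)
                frozen[c] = (sdf_p, sdf_d, vis, view["camera"])
            k = min(schedule.render_every, max_iter - done)
            p, energies = _lm_minimize(
                lambda q: residual_keypoint(q, frozen), p, k, schedule)
            trace.append(energies)
            done += k
            if len(energies) <= 1:     # no accepted step: converged
                break
    return _unpack(p, n_active, schedule), trace


# ---------------------------------------------------------------------------
# sequence driver
# ---------------------------------------------------------------------------

def baseline_triangulate(cues: dict[int, np.ndarray],
                         cameras: list[CameraModel]) -> np.ndarray:
    """Per-keypoint MLE triangulation baseline; NaN rows where < 2 views see it."""
    n_k = next(iter(cues.values())).shape[0]
    out = np.full((n_k, 3), np.nan)
    for m in range(n_k):
        obs = [Observation2D(c, y[m, :2], y[m, 2])
               for c, y in cues.items() if y[m, 2] > 0]
        if len({o.view for o in obs}) < 2:
            continue
        X, _ = triangulate_mle(obs, cameras)
        if X is not None:
            out[m] = X
    return out


def _cues_for_group(frame: FrameDetections, group) -> dict[int, np.ndarray]:
    return {c: frame.views[c][q].keypoints.copy() for c, q in group}


def _views_seen(cues: dict[int, np.ndarray], n_k: int) -> np.ndarray:
    seen = np.zeros(n_k, dtype=int)
    for y in cues.values():
        seen += (y[:, 2] > 0).astype(int)
    return seen


def fit_sequence(model: ArticulatedModel,
                 detections: list[FrameDetections],
                 cameras: list[CameraModel],
                 library: AnchorPoseLibrary,
                 n_individuals: int,
                 weights_init: EnergyWeights | None = None,
                 weights_track: EnergyWeights | None = None,
                 schedule: FitSchedule | None = None,
                 edge_cutoff: float = 25.0,
                 track_gate: float = 50.0,
                 use_silhouettes: bool = False,
                 gap_limit: int = 10,
                 removal_log: list | None = None) -> list[list[FittedState]]:
    """Full pipeline over a time-ordered frame sequence.

    Frame 0: spatial graph partitioning, anchor-pose retrieval and an
    initialization fit.  Later frames: Hungarian tracking against the
    projected previous keypoints, occlusion-aware cue filtering (when
    silhouettes are in play) and a short tracking fit.  A keypoint is
    "invisible" when seen by <= 1 view; it is still reported, inferred through
    the mesh.  Identities unseen in all views for more than ``gap_limit``
    frames are marked broken but keep being propagated on priors.  Every cue
    removed by occlusion filtering is appended to ``removal_log`` (when
    given) and emitted as a JSON log line for auditability.
    """
    weights_init = weights_init or EnergyWeights.for_init()
    weights_track = weights_track or EnergyWeights.for_tracking()
    schedule = schedule or FitSchedule()
    n_k = model.n_keypoints
    # silhouette work happens in the mask pixel grid of the detections
    work_scale = (detections[0].mask_scale if use_silhouettes and detections
                  else schedule.raster_scale)
    states: list[list[FittedState]] = []
    poses: list[PoseParams] = []
    anchors: list[PoseParams] = []
    missing_streak = [0] * n_individuals

    for t, frame in enumerate(detections):
        frame_states = []
        if t == 0:
            graph = build_association_graph(frame, cameras, edge_cutoff)
            grouping = partition_graph(graph, n_individuals)
        else:
            prev_kps = [lbs_keypoints(model, p) for p in poses]
            grouping = track_frame(prev_kps, frame, cameras, track_gate)
            if use_silhouettes:
                surfaces = [lbs_pose(model, p) for p in poses]
                rendered = rasterize_depth(cameras, surfaces, model.faces,
                                           work_scale)
                dropped: list = []
                frame = filter_occluded_cues(grouping, rendered, frame,
                                             schedule.rho_occ,
                                             schedule.delta_z,
                                             det_scale=work_scale,
                                             log=dropped)
                for entry in dropped:
                    entry = {"stage": "filter_occluded_cues",
                             "frame": t, **entry}
                    logger.info(json.dumps(
                        entry,
                        default=lambda o: o.item()
                        if hasattr(o, "item") else str(o)))
                    if removal_log is not None:
                        removal_log.append(entry)
        for ident in range(n_individuals):
            group = (grouping.groups[ident]
                     if ident < len(grouping.groups) else [])
            cues = _cues_for_group(frame, group)
            sdfs = None
            if use_silhouettes:
                sdfs = {}
                for c, q in group:
                    inst = frame.views[c][q]
                    if inst.mask is not None and inst.mask.any():
                        sdfs[c] = sdf_from_mask(inst.mask)
                sdfs = sdfs or None
            if t == 0:
                _, init_pose, _ = retrieve_anchor_pose(
                    library, cues, cameras, model, schedule=schedule)
                anchors.append(init_pose.copy())
                pose, trace = fit_frame(
                    model, init_pose, cues, cameras, weights_init, schedule,
                    mode="init", anchor=init_pose, detected_sdfs=sdfs,
                    sdf_scale=work_scale)
                poses.append(pose)
            else:
                if not cues:
                    missing_streak[ident] += 1
                else:
                    missing_streak[ident] = 0
                pose, trace = fit_frame(
                    model, poses[ident], cues, cameras, weights_track,
                    schedule, mode="track", prev_pose=poses[ident],
                    detected_sdfs=sdfs, sdf_scale=work_scale)
                poses[ident] = pose
            X = lbs_keypoints(model, poses[ident])
            frame_states.append(FittedState(
                frame=t, identity=ident, pose=poses[ident].copy(),
                keypoints=X, n_views_seen=_views_seen(cues, n_k),
                broken=missing_streak[ident] > gap_limit,
                energy_trace=trace))
        states.append(frame_states)
    return states
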