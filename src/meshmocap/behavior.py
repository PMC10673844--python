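"""Behavior analytics on fitted 3D trajectories.

Covers four analysis families:

* animal-scene interaction (drinking near a water tap, feeding inside a
  trough volume), judged from the reconstructed nose trajectory;
* dyadic social behaviors from surface-to-surface geometry: the head-to-body
  minimum distance ``d_h(A, B)``, the body part of the closest vertex, the
  top-view convex-hull overlap ``o(A, B)`` and the body pitch drive
  rule-based classification of Approach/Leave, Head-X contacts and Mount;
* posture discovery: a 178-dimensional per-frame feature vector (keypoint
  positions and velocities, tail/center heights, body pitch/roll, selected
  joint rotations) is reduced by PCA and t-SNE, and posture clusters are the
  watershed basins of the inverted embedding density;
* tail kinematics: a signed tail bend angle and its Welch power spectral
  density, with a fixed spectral power threshold separating loose wagging
  from passive hanging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from shapely.geometry import MultiPoint

from .model_core import (ArticulatedModel, PoseParams, PosedSurface,
                         downsample_vertices)

__all__ = [
    "SocialConfig",
    "BehaviorEvent",
    "detect_drinking",
    "detect_feeding",
    "pairwise_surface_stats",
    "classify_social",
    "posture_features",
    "posture_map",
    "tail_angle",
    "tail_psd",
    "default_feature_joints",
]


@dataclass
class SocialConfig:
    """Thresholds for the dyadic social behavior rules.

    Distances in meters, the mount pitch threshold in degrees (converted to
    radians internally), the event window in frames.
    """

    contact_on: float = 0.05
    contact_off: float = 0.2
    mount_pitch_deg: float = 20.0
    mount_overlap: float = 0.15
    window: int = 12
    downsample_count: int = 546

    def __post_init__(self):
        if not self.contact_on < self.contact_off:
            raise ValueError("contact_on must be below contact_off")
        if min(self.contact_on, self.mount_pitch_deg,
               self.mount_overlap) <= 0 or self.window <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class BehaviorEvent:
    """A contiguous run of frames in which one behavior rule holds."""

    kind: str
    actor: int
    target: int | str
    start: int
    end: int            # inclusive


# ---------------------------------------------------------------------------
# animal-scene interaction
# ---------------------------------------------------------------------------

def detect_drinking(nose_traj: np.ndarray, tap_position: np.ndarray,
                    threshold: float = 0.12) -> np.ndarray:
    """Frames where the nose is within ``threshold`` meters of the water tap."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    nose = np.atleast_2d(np.asarray(nose_traj, float))
    d = np.linalg.norm(nose - np.asarray(tap_position, float), axis=1)
    return d < threshold


def detect_feeding(nose_traj: np.ndarray, cube_min: np.ndarray,
                   cube_extent: np.ndarray = (0.62, 0.7, 0.2)) -> np.ndarray:
    """Frames where the nose lies inside the half-open feeding box
    ``[min, min + extent)``; the default extent is the trough volume."""
    nose = np.atleast_2d(np.asarray(nose_traj, float))
    lo = np.asarray(cube_min, float)
    hi = lo + np.asarray(cube_extent, float)
    if np.any(hi <= lo):
        raise ValueError("cube extent must be positive")
    return np.all((nose >= lo) & (nose < hi), axis=1)


# ---------------------------------------------------------------------------
# dyadic surface statistics + rules
# ---------------------------------------------------------------------------

def pairwise_surface_stats(surface_a: PosedSurface, surface_b: PosedSurface,
                           model: ArticulatedModel,
                           pose_a: PoseParams | None = None,
                           config: SocialConfig | None = None) -> dict:
    """Geometry between an actor A and a target B for the social rules.

    ``d_h`` is the minimum distance from A's head vertices to B's
    (downsampled) surface, ``part`` the body part of the closest B vertex,
    ``overlap`` the xy convex-hull IoU of the two downsampled vertex clouds,
    and ``pitch_a`` the actor's body pitch r_y (radians, available when
    ``pose_a`` is given).
    """
    config = config or SocialConfig()
    sub = downsample_vertices(model, min(config.downsample_count,
                                         model.n_vertices))
    head = model.head_vertex_indices()
    va = surface_a.vertices[head]
    vb = surface_b.vertices[sub]
    d = np.linalg.norm(vb[:, None, :] - va[None, :, :], axis=2)
    flat = int(np.argmin(d))
    bi = flat // va.shape[0]
    d_h = float(d.flat[flat])
    part = str(model.part_label[sub[bi]])
    hull_a = MultiPoint(surface_a.vertices[sub, :2]).convex_hull
    hull_b = MultiPoint(vb[:, :2]).convex_hull
    inter = hull_a.intersection(hull_b).area
    union = hull_a.union(hull_b).area
    overlap = float(inter / union) if union > 0 else 0.0
    pitch = float(pose_a.global_rot[1]) if pose_a is not None else 0.0
    return {"d_h": d_h, "part": part, "overlap": overlap, "pitch_a": pitch}


def _merge_runs(flags: np.ndarray, kind: str, actor, target
                ) -> list[BehaviorEvent]:
    events = []
    start = None
    for t, on in enumerate(flags):
        if on and start is None:
            start = t
        elif not on and start is not None:
            events.append(BehaviorEvent(kind, actor, target, start, t - 1))
            start = None
    if start is not None:
        events.append(BehaviorEvent(kind, actor, target, start,
                                    len(flags) - 1))
    return events


def classify_social(stats: dict[str, np.ndarray], actor: int, target: int,
                    config: SocialConfig | None = None
                    ) -> list[BehaviorEvent]:
    """Rule-based dyadic behavior events for the ordered pair (actor, target).

    ``stats`` holds per-frame arrays ``d_h``, ``part``, ``overlap``,
    ``pitch_a``.  Dynamic rules look ``window`` frames back and forward
    (Approach: far then close; Leave: close then far); static contact rules
    fire on the instantaneous distance and closest part; Mount on pitch and
    top-view overlap.  Contiguous positive frames merge into one event.
    Series shorter than 2*window+1 skip the dynamic rules.
    """
    config = config or SocialConfig()
    d_h = np.asarray(stats["d_h"], float)
    part = np.asarray(stats["part"])
    overlap = np.asarray(stats["overlap"], float)
    pitch = np.asarray(stats["pitch_a"], float)
    n = d_h.size
    W = config.window
    events: list[BehaviorEvent] = []

    if n >= 2 * W + 1:
        approach = np.zeros(n, bool)
        leave = np.zeros(n, bool)
        for t in range(W, n - W):
            approach[t] = (d_h[t - W] > config.contact_off
                           and d_h[t + W] < config.contact_on)
            leave[t] = (d_h[t - W] < config.contact_on
                        and d_h[t + W] > config.contact_off)
        events += _merge_runs(approach, "Approach", actor, target)
        events += _merge_runs(leave, "Leave", actor, target)

    contact = d_h < config.contact_on
    for part_name, kind in (("head", "Head-Head"), ("body", "Head-Body"),
                            ("limb", "Head-Limb"), ("tail", "Head-Tail")):
        events += _merge_runs(contact & (part == part_name), kind,
                              actor, target)
    mount = ((pitch > np.deg2rad(config.mount_pitch_deg))
             & (overlap > config.mount_overlap))
    events += _merge_runs(mount, "Mount", actor, target)
    events.sort(key=lambda e: (e.start, e.kind))
    return events


# ---------------------------------------------------------------------------
# posture discovery
# ---------------------------------------------------------------------------

def default_feature_joints(model: ArticulatedModel) -> np.ndarray:
    """The 22 joints whose rotations enter the posture feature vector:
    the active set minus the two most distal tail joints."""
    names = [model.joint_names[j] for j in model.active_joints]
    drop = {"tail_7", "tail_8"}
    keep = [i for i, n in enumerate(names) if n not in drop]
    if len(keep) > 22:
        keep = keep[:22]
    return np.array(keep, int)


def posture_features(keypoints: np.ndarray, poses: list[PoseParams],
                     model: ArticulatedModel, frame_rate: float = 25.0,
                     feature_joints: np.ndarray | None = None) -> np.ndarray:
    """Per-frame 178-dim posture descriptors from normalized poses.

    ``keypoints`` is (T, N_K, 3) regressed from the *normalized* poses
    (global xy translation, heading and scale removed).  Layout: 19 keypoint
    positions (57), 17 keypoint velocities excluding the ears (51, central
    differences scaled by the frame rate), tail-root and center heights (2),
    body pitch and roll (2), axis-angle rotations of 22 joints (66).
    """
    kp = np.asarray(keypoints, float)
    T = kp.shape[0]
    if T < 3:
        raise ValueError("need at least 3 frames for velocity features")
    names = model.keypoint_names
    ears = [i for i, n in enumerate(names) if n in ("l_ear", "r_ear")]
    vel_idx = [i for i in range(len(names)) if i not in ears]
    vel = np.gradient(kp, axis=0) * frame_rate       # central differences
    i_tail = names.index("tail_root")
    i_center = names.index("center")
    fj = (default_feature_joints(model) if feature_joints is None
          else feature_joints)
    rows = []
    for t in range(T):
        pose = poses[t]
        rows.append(np.concatenate([
            kp[t].ravel(),                             # 57
            vel[t, vel_idx].ravel(),                   # 51
            [kp[t, i_tail, 2], kp[t, i_center, 2]],    # 2
            [pose.global_rot[1], pose.global_rot[2]],  # pitch, roll
            pose.theta[fj].ravel(),                    # 66
        ]))
    return np.array(rows)


def posture_map(features: np.ndarray, seed: int = 0, perplexity: float = 80.0,
                bandwidth: float = 0.03, grid: int = 200,
                n_components: int = 16,
                peak_prominence: float = 0.1,
                saddle_merge_ratio: float = 0.2) -> dict:
    """Embed posture features and segment the density into posture blocks.

    PCA to ``n_components`` dims, t-SNE to 2D at the given perplexity, both
    embedding axes min-max normalized to [0.05, 0.95]; Gaussian KDE on a
    raster grid (density normalized to [0, 1]); the watershed transform of
    the inverted density map yields labeled blocks, each with one local
    density peak.  Watershed markers are the h-maxima of the density, so
    peaks whose prominence is below ``peak_prominence`` (fraction of the
    density maximum) merge into their dominant neighbor instead of spawning
    spurious blocks; adjacent basins whose shared saddle is high relative to
    the weaker peak (``saddle_merge_ratio``) are merged afterwards, the
    usual persistence cure for watershed over-segmentation.
    """
    from scipy.ndimage import label as ndlabel
    from skimage.morphology import h_maxima
    from skimage.segmentation import watershed
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE
    from sklearn.neighbors import KernelDensity

    X = np.asarray(features, float)
    n = X.shape[0]
    if n < 100:
        raise ValueError("need at least 100 samples")
    if n < 3 * perplexity:
        raise ValueError(
            f"n={n} too small for perplexity {perplexity}; use a smaller one")
    pca = PCA(n_components=min(n_components, X.shape[1]), random_state=seed)
    Z = pca.fit_transform(X)
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(Z)
    lo, hi = emb.min(axis=0), emb.max(axis=0)
    emb = 0.05 + 0.9 * (emb - lo) / np.maximum(hi - lo, 1e-12)

    kde = KernelDensity(bandwidth=bandwidth).fit(emb)
    axis = np.linspace(0.0, 1.0, grid)
    gx, gy = np.meshgrid(axis, axis)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    density = np.exp(kde.score_samples(pts)).reshape(grid, grid)
    density = density / density.max()

    markers, _ = ndlabel(h_maxima(density, peak_prominence))
    labels = watershed(1.0 - density, markers, mask=density > 1e-3)
    labels = _merge_shallow_basins(labels, density, saddle_merge_ratio)

    rows = np.clip((emb[:, 1] * (grid - 1)).round().astype(int), 0, grid - 1)
    cols = np.clip((emb[:, 0] * (grid - 1)).round().astype(int), 0, grid - 1)
    block = labels[rows, cols]
    dens_at = density[rows, cols]
    peak_samples = {}
    for b in np.unique(block):
        if b == 0:
            continue
        members = np.where(block == b)[0]
        peak_samples[int(b)] = int(members[np.argmax(dens_at[members])])
    return {"embedding": emb, "density": density, "labels": labels,
            "block": block, "peak_samples": peak_samples,
            "explained_variance": float(pca.explained_variance_ratio_.sum())}


# ---------------------------------------------------------------------------
# tail kinematics
# ---------------------------------------------------------------------------

def _merge_shallow_basins(labels: np.ndarray, density: np.ndarray,
                          ratio: float) -> np.ndarray:
    """Union adjacent watershed basins separated by a shallow saddle.

    Two basins merge when the highest density on their shared boundary
    exceeds ``ratio`` times the weaker basin's peak density; deep valleys
    (saddle near zero) stay split.
    """
    if ratio <= 0:
        return labels
    peaks = {b: density[labels == b].max()
             for b in np.unique(labels) if b > 0}
    saddles: dict[tuple, float] = {}
    for shift in ((0, 1), (1, 0)):
        a = labels[:labels.shape[0] - shift[0], :labels.shape[1] - shift[1]]
        b = labels[shift[0]:, shift[1]:]
        da = density[:a.shape[0], :a.shape[1]]
        db = density[shift[0]:, shift[1]:]
        touch = (a > 0) & (b > 0) & (a != b)
        for l1, l2, s in zip(a[touch], b[touch],
                             np.minimum(da[touch], db[touch])):
            key = (min(l1, l2), max(l1, l2))
            saddles[key] = max(saddles.get(key, 0.0), float(s))
    parent = {b: b for b in peaks}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (l1, l2), s in saddles.items():
        if s > ratio * min(peaks[l1], peaks[l2]):
            parent[find(l1)] = find(l2)
    out = labels.copy()
    remap = {}
    for b in peaks:
        root = find(b)
        remap.setdefault(root, len(remap) + 1)
        out[labels == b] = remap[root]
    return out


def tail_angle(tail_joints: np.ndarray, body_center: np.ndarray) -> float:
    """Signed tail bend angle from the 8-joint tail chain (root to tip).

    ``a`` points from tail_1 to tail_2 and ``b`` from tail_7 to tail_8;
    the magnitude is ``|arccos(a.b)|`` and the sign is positive when the tip
    lies on the left of the plane through tail_1, tail_2 and the body center
    (left = the side the plane normal ``(tail_2 - tail_1) x (center - tail_1)``
    points to).
    """
    t = np.asarray(tail_joints, float)
    if t.shape[0] < 8:
        raise ValueError("need 8 tail joints root-to-tip")
    a = t[1] - t[0]
    b = t[7] - t[6]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("degenerate tail chain: coincident joints")
    a, b = a / na, b / nb
    mag = float(np.abs(np.arccos(np.clip(a @ b, -1.0, 1.0))))
    normal = np.cross(t[1] - t[0], np.asarray(body_center, float) - t[0])
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate sign plane: center collinear with tail")
    sgn = 1.0 if float(normal @ (t[7] - t[0])) >= 0 else -1.0
    return sgn * mag


def tail_psd(theta_trace: np.ndarray, fs: float = 25.0, nperseg: int = 200,
             threshold: float = 1.5) -> dict:
    """Welch power spectral density of the tail-angle trace.

    Frequency bins fall on multiples of fs/nperseg (0.125 Hz at defaults);
    ``wagging`` is declared when the maximum PSD exceeds ``threshold``
    (linear units).  Traces shorter than one segment are an error.
    """
    x = np.asarray(theta_trace, float)
    if x.size < nperseg:
        raise ValueError(f"trace length {x.size} < nperseg {nperseg}")
    freqs, psd = welch(x, fs=fs, nperseg=nperseg)
    peak = int(np.argmax(psd))
    return {"frequencies": freqs, "psd": psd,
            "peak_freq": float(freqs[peak]),
            "wagging": bool(psd.max() > threshold)}
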