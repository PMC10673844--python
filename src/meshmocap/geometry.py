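"""Multi-view camera geometry: projection, epipolar distances, triangulation, PnP.

Cameras follow the pinhole model with optional 5-parameter Brown-Conrady
distortion (k1, k2, p1, p2, k3).  World-to-camera mapping is
``x_cam = R @ X + t``; pixel coordinates are 0-based with the origin at the
top-left corner, x right, y down.  Mask arrays are indexed ``[row, col]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares

__all__ = [
    "CameraModel",
    "Observation2D",
    "project",
    "fundamental_matrix",
    "epipolar_distance",
    "triangulate_dlt",
    "triangulate_mle",
    "calibrate_extrinsics_pnp",
    "load_calibration",
    "save_calibration",
]


@dataclass
class CameraModel:
    """Calibrated pinhole camera."""

    intrinsics: np.ndarray                  # (3, 3) K
    rotation: np.ndarray                    # (3, 3) world->camera R
    translation: np.ndarray                 # (3,) world->camera t, meters
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))
    image_size: tuple[int, int] = (1920, 1080)   # (width, height)

    def __post_init__(self):
        self.intrinsics = np.asarray(self.intrinsics, float)
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float).ravel()
        self.distortion = np.asarray(self.distortion, float).ravel()
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be a proper rotation (det = 1)")
        if self.intrinsics[0, 0] <= 0 or self.intrinsics[1, 1] <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (-R^T t)."""
        return -self.rotation.T @ self.translation

    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix K [R | t] (valid for zero distortion)."""
        return self.intrinsics @ np.hstack(
            [self.rotation, self.translation[:, None]])

    def scaled(self, factor: float) -> "CameraModel":
        """Camera for an image resized by ``factor`` (same field of view)."""
        K = self.intrinsics.copy()
        K[:2] *= factor
        w, h = self.image_size
        return CameraModel(K, self.rotation, self.translation,
                           self.distortion,
                           (int(round(w * factor)), int(round(h * factor))))


@dataclass
class Observation2D:
    """A 2D keypoint observation in one view; sigma = 0 means invisible."""

    view: int
    point: np.ndarray
    confidence: float = 1.0

    def __post_init__(self):
        self.point = np.asarray(self.point, float).ravel()


def _distort(xn: np.ndarray, dist: np.ndarray) -> np.ndarray:
    k1, k2, p1, p2, k3 = dist
    x, y = xn[:, 0], xn[:, 1]
    r2 = x * x + y * y
    radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=1)


def _undistort(pix: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Iteratively invert the distortion; returns ideal pixel coordinates."""
    if not np.any(cam.distortion):
        return pix
    K = cam.intrinsics
    xn = (pix - K[:2, 2]) / np.array([K[0, 0], K[1, 1]])
    xu = xn.copy()
    for _ in range(10):
        delta = _distort(xu, cam.distortion) - xu
        xu = xn - delta
    return xu * np.array([K[0, 0], K[1, 1]]) + K[:2, 2]


def project(camera: CameraModel, points: np.ndarray,
            return_valid: bool = False):
    """Project world points to pixel coordinates.

    Points at or behind the camera plane (depth <= 0) are flagged invalid
    rather than producing NaNs.

    Returns ``pixels`` or ``(pixels, valid, depth)`` when ``return_valid``.
    """
    points = np.atleast_2d(np.asarray(points, float))
    cam_pts = points @ camera.rotation.T + camera.translation
    depth = cam_pts[:, 2]
    valid = depth > 1e-9
    safe = np.where(valid, depth, 1.0)
    xn = cam_pts[:, :2] / safe[:, None]
    if np.any(camera.distortion):
        xn = _distort(xn, camera.distortion)
    K = camera.intrinsics
    pix = xn * np.array([K[0, 0], K[1, 1]]) + K[:2, 2]
    pix[~valid] = np.nan
    if return_valid:
        return pix, valid, depth
    return pix


def fundamental_matrix(cam_a: CameraModel, cam_b: CameraModel) -> np.ndarray:
    """Fundamental matrix mapping points in view a to epipolar lines in b."""
    R = cam_b.rotation @ cam_a.rotation.T
    t = cam_b.translation - R @ cam_a.translation
    if np.linalg.norm(cam_a.center - cam_b.center) < 1e-12:
        raise ValueError("degenerate camera pair: identical centers")
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    E = tx @ R
    return np.linalg.inv(cam_b.intrinsics).T @ E @ np.linalg.inv(
        cam_a.intrinsics)


def _point_line_dist(pts: np.ndarray, lines: np.ndarray) -> np.ndarray:
    num = np.abs(np.sum(lines[:, :2] * pts, axis=1) + lines[:, 2])
    den = np.linalg.norm(lines[:, :2], axis=1)
    return num / np.maximum(den, 1e-300)


def epipolar_distance(cam_a: CameraModel, cam_b: CameraModel,
                      kpts_a: np.ndarray, kpts_b: np.ndarray) -> float | None:
    """Mean symmetric point-to-epipolar-line distance over shared keypoints.

    ``kpts_*`` are (N_K, 3) arrays of (x, y, sigma); only keypoints visible
    (sigma > 0) in *both* views contribute.  Returns None when no keypoint is
    shared.  Distorted observations are undistorted before the epipolar math.
    """
    kpts_a = np.asarray(kpts_a, float)
    kpts_b = np.asarray(kpts_b, float)
    shared = (kpts_a[:, 2] > 0) & (kpts_b[:, 2] > 0)
    if not np.any(shared):
        return None
    pa = _undistort(kpts_a[shared, :2], cam_a)
    pb = _undistort(kpts_b[shared, :2], cam_b)
    F = fundamental_matrix(cam_a, cam_b)
    ha = np.hstack([pa, np.ones((pa.shape[0], 1))])
    hb = np.hstack([pb, np.ones((pb.shape[0], 1))])
    d_ab = _point_line_dist(pb, ha @ F.T)   # lines in b from points in a
    d_ba = _point_line_dist(pa, hb @ F)     # lines in a from points in b
    return float(np.mean(0.5 * (d_ab + d_ba)))


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def _valid_obs(observations, cameras):
    obs = [o for o in observations if o.confidence > 0]
    views = {o.view for o in obs}
    return obs, views


def triangulate_dlt(observations: list[Observation2D],
                    cameras: list[CameraModel]) -> np.ndarray | None:
    """Linear (DLT) triangulation; returns None when under-constrained."""
    obs, views = _valid_obs(observations, cameras)
    if len(views) < 2:
        return None
    rows = []
    for o in obs:
        cam = cameras[o.view]
        pix = _undistort(o.point[None, :], cam)[0]
        P = cam.projection_matrix()
        rows.append(pix[0] * P[2] - P[0])
        rows.append(pix[1] * P[2] - P[1])
    A = np.array(rows)
    _, _, vt = np.linalg.svd(A)
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-15:
        return None
    return Xh[:3] / Xh[3]


def _reproj_residuals(X, observations, cameras, weighted):
    res = []
    for o in observations:
        if o.confidence <= 0:
            continue
        cam = cameras[o.view]
        pix = project(cam, X[None, :])[0]
        target = o.point
        r = pix - target
        if not np.all(np.isfinite(r)):
            r = np.array([1e6, 1e6])
        if weighted:
            r = r * np.sqrt(o.confidence)
        res.extend(r)
    return np.array(res)


def triangulate_mle(observations: list[Observation2D],
                    cameras: list[CameraModel],
                    weighted: bool = False):
    """Maximum-likelihood triangulation: DLT init + iterative refinement.

    Minimizes the sum of squared per-view reprojection errors (optionally
    sigma-weighted).  Returns ``(point, rms_residual_px)`` or
    ``(None, None)`` when fewer than 2 views see the point.
    """
    X0 = triangulate_dlt(observations, cameras)
    if X0 is None:
        return None, None
    sol = least_squares(
        _reproj_residuals, X0, args=(observations, cameras, weighted),
        method="lm", max_nfev=200)
    return sol.x, reprojection_residual(sol.x, observations, cameras)


def reprojection_residual(X, observations, cameras) -> float:
    """RMS per-view reprojection error of a 3D point (pixels)."""
    res = _reproj_residuals(np.asarray(X, float), observations, cameras, False)
    return float(np.sqrt(np.mean(
        np.sum(res.reshape(-1, 2) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# PnP extrinsic calibration
# ---------------------------------------------------------------------------

def calibrate_extrinsics_pnp(scene_points: np.ndarray,
                             image_points: np.ndarray,
                             K: np.ndarray,
                             distortion: np.ndarray | None = None):
    """Estimate camera pose (R, t) from 3D-2D correspondences.

    DLT on normalized coordinates followed by Levenberg-Marquardt refinement
    of the reprojection error.  Returns ``(R, t, rms_px)``.
    """
    X = np.asarray(scene_points, float)
    x = np.asarray(image_points, float)
    K = np.asarray(K, float)
    if X.shape[0] < 6:
        raise ValueError("PnP requires at least 6 correspondences")
    cam0 = CameraModel(K, np.eye(3), np.zeros(3),
                       np.zeros(5) if distortion is None else distortion)
    xu = _undistort(x, CameraModel(K, np.eye(3), np.zeros(3),
                                   cam0.distortion))
    xn = (xu - K[:2, 2]) / np.array([K[0, 0], K[1, 1]])
    # DLT for the 3x4 pose [R|t] in normalized coordinates
    n = X.shape[0]
    A = np.zeros((2 * n, 12))
    for i in range(n):
        Xi = np.append(X[i], 1.0)
        A[2 * i, 0:4] = Xi
        A[2 * i, 8:12] = -xn[i, 0] * Xi
        A[2 * i + 1, 4:8] = Xi
        A[2 * i + 1, 8:12] = -xn[i, 1] * Xi
    _, sv, vt = np.linalg.svd(A)
    if sv[-2] < 1e-12 * sv[0]:
        raise ValueError("rank-deficient correspondence configuration")
    P = vt[-1].reshape(3, 4)
    # fix sign so points are in front of the camera
    if np.median(P[2] @ np.hstack([X, np.ones((n, 1))]).T) < 0:
        P = -P
    M = P[:, :3]
    U, s, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
        P = -P
        U, s, Vt = np.linalg.svd(-M)
    scale = np.mean(s)
    t = P[:, 3] / scale

    def pack_residual(p):
        from .model_core import axis_angle_to_matrix
        Rr = axis_angle_to_matrix(p[:3])
        cam = CameraModel(K, Rr, p[3:6], cam0.distortion)
        pix = project(cam, X)
        r = (pix - x).ravel()
        r[~np.isfinite(r)] = 1e6
        return r

    # axis-angle from R for the refinement parameterization
    from scipy.spatial.transform import Rotation
    p0 = np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
    sol = least_squares(pack_residual, p0, method="lm", max_nfev=500)
    Rf = Rotation.from_rotvec(sol.x[:3]).as_matrix()
    tf = sol.x[3:6]
    resid = pack_residual(sol.x).reshape(-1, 2)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Rf, tf, rms


# ---------------------------------------------------------------------------
# calibration I/O
# ---------------------------------------------------------------------------

def _cam_to_dict(cam: CameraModel) -> dict:
    return {"K": cam.intrinsics.tolist(), "dist": cam.distortion.tolist(),
            "R": cam.rotation.tolist(), "t": cam.translation.tolist(),
            "size": list(cam.image_size), "schema_version": 1}


def _cam_from_dict(d: dict) -> CameraModel:
    return CameraModel(np.array(d["K"]), np.array(d["R"]),
                       np.array(d["t"]), np.array(d.get("dist", np.zeros(5))),
                       tuple(d.get("size", (1920, 1080))))


def save_calibration(cameras: list[CameraModel], path) -> None:
    """Write all cameras to one YAML (or JSON, by extension) file."""
    path = Path(path)
    payload = {"cameras": [_cam_to_dict(c) for c in cameras]}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload))
    else:
        path.write_text(yaml.safe_dump(payload))


def load_calibration(path) -> list[CameraModel]:
    """Load cameras from a YAML/JSON file or a directory of per-view files."""
    path = Path(path)
    if path.is_dir():
        cams = []
        for f in sorted(path.iterdir()):
            if f.suffix in (".yaml", ".yml", ".json"):
                cams.extend(load_calibration(f))
        return cams
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "cameras" in data:
        return [_cam_from_dict(d) for d in data["cameras"]]
    return [_cam_from_dict(data)]
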