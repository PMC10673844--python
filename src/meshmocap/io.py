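"""File formats and run configuration.

Detections travel as COCO-flavored JSON: an ``images`` list (one entry per
frame/view) and an ``annotations`` list (one entry per detected instance,
with ``bbox`` [x, y, w, h], ``keypoints`` as flat [x, y, sigma] triplets and
``segmentation`` as either an uncompressed column-major run-length encoding
or a PNG file reference).  Calibration uses the YAML/JSON dialect of
:mod:`meshmocap.geometry`.  Fitted trajectories are written as a pose JSON
plus a flat keypoint CSV.  Every run can emit a manifest (config hash, seed,
version) sufficient to reproduce deterministic stages bit-for-bit.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .association import FrameDetections, IdentityGrouping, Instance
from .fitting import EnergyWeights, FitSchedule, FittedState
from .model_core import PoseParams

__all__ = [
    "RunConfig",
    "rle_encode",
    "rle_decode",
    "write_detections",
    "read_detections",
    "write_grouping",
    "read_grouping",
    "write_fitted_states",
    "read_fitted_states",
    "write_manifest",
    "mpjpe",
]

SCHEMA_VERSION = 1
_KNOWN_IMAGE_KEYS = {"id", "frame", "view", "width", "height"}
_KNOWN_ANN_KEYS = {"id", "image_id", "bbox", "keypoints", "segmentation",
                   "score"}


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    model_mesh: str = ""
    model_skeleton: str = ""
    calibration: str = ""
    detections: str = ""
    output: str = ""
    n_individuals: int = 1
    seed: int = 0
    frame_range: tuple[int, int] | None = None
    frame_rate: float = 25.0
    edge_cutoff: float = 25.0
    track_gate: float = 50.0
    use_silhouettes: bool = False
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    schedule: FitSchedule = field(default_factory=FitSchedule)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "weights" in d and isinstance(d["weights"], dict):
            d["weights"] = EnergyWeights(**d["weights"])
        if "schedule" in d and isinstance(d["schedule"], dict):
            sched = dict(d["schedule"])
            if "scale_bounds" in sched:
                sched["scale_bounds"] = tuple(sched["scale_bounds"])
            d["schedule"] = FitSchedule(**sched)
        if d.get("frame_range") is not None:
            d["frame_range"] = tuple(d["frame_range"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed column-major RLE (counts start with background)."""
    mask = np.asarray(mask).astype(bool)
    flat = mask.T.ravel()                        # column-major
    counts = []
    prev, run = False, 0
    for v in flat:
        if v == prev:
            run += 1
        else:
            counts.append(run)
            prev, run = v, 1
    counts.append(run)
    return {"size": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape(w, h).T


def _mask_to_payload(mask, mask_dir: Path | None, name: str):
    if mask is None:
        return None
    if mask_dir is not None:
        from PIL import Image
        mask_dir.mkdir(parents=True, exist_ok=True)
        fname = f"{name}.png"
        Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)
                        ).save(mask_dir / fname)
        return {"png": fname}
    return {"rle": rle_encode(mask)}


def _mask_from_payload(seg, base_dir: Path, where: str):
    if seg is None:
        return None
    if "rle" in seg:
        return rle_decode(seg["rle"])
    if "png" in seg:
        from PIL import Image
        path = base_dir / seg["png"]
        if not path.exists():
            raise FileNotFoundError(
                f"mask file {seg['png']} missing for {where}")
        return np.asarray(Image.open(path)) > 127
    raise ValueError(f"unknown segmentation payload for {where}")


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def write_detections(frames: list[FrameDetections], path,
                     png_masks: bool = False) -> None:
    """Serialize per-frame detections to COCO-flavored JSON.

    With ``png_masks`` silhouettes go to PNG files next to the JSON;
    otherwise they are embedded as uncompressed RLE.
    """
    path = Path(path)
    mask_dir = path.parent / (path.stem + "_masks") if png_masks else None
    images, annotations = [], []
    img_id = ann_id = 0
    for f, frame in enumerate(frames):
        for c in sorted(frame.views):
            images.append({"id": img_id, "frame": f, "view": c})
            for q, inst in enumerate(frame.views[c]):
                annotations.append({
                    "id": ann_id, "image_id": img_id,
                    "bbox": np.asarray(inst.bbox, float).tolist(),
                    "keypoints": np.asarray(inst.keypoints,
                                            float).ravel().tolist(),
                    "segmentation": _mask_to_payload(
                        inst.mask, mask_dir, f"f{f}_v{c}_i{q}"),
                })
                ann_id += 1
            img_id += 1
    payload = {"schema_version": SCHEMA_VERSION,
               "mask_scale": frames[0].mask_scale if frames else 1.0,
               "images": images, "annotations": annotations}
    path.write_text(json.dumps(payload))


def read_detections(path, expected_keypoints: int | None = None
                    ) -> list[FrameDetections]:
    """Parse detections JSON back into per-frame structures.

    Unknown fields are ignored with a warning; a keypoint count differing
    from ``expected_keypoints`` is an error.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    for img in data["images"][:1]:
        extra = set(img) - _KNOWN_IMAGE_KEYS
        if extra:
            warnings.warn(f"ignoring unknown image fields {sorted(extra)}")
    for ann in data["annotations"][:1]:
        extra = set(ann) - _KNOWN_ANN_KEYS
        if extra:
            warnings.warn(f"ignoring unknown annotation fields "
                          f"{sorted(extra)}")
    img_info = {img["id"]: (img["frame"], img["view"])
                for img in data["images"]}
    n_frames = 1 + max((f for f, _ in img_info.values()), default=-1)
    frames = [FrameDetections(mask_scale=data.get("mask_scale", 1.0))
              for _ in range(n_frames)]
    for img in data["images"]:
        frames[img["frame"]].views.setdefault(img["view"], [])
    for ann in data["annotations"]:
        f, c = img_info[ann["image_id"]]
        kps = np.asarray(ann["keypoints"], float).reshape(-1, 3)
        if expected_keypoints is not None and kps.shape[0] != expected_keypoints:
            raise ValueError(
                f"annotation {ann['id']} has {kps.shape[0]} keypoints, "
                f"model expects {expected_keypoints}")
        mask = _mask_from_payload(
            ann.get("segmentation"),
            path.parent / (path.stem + "_masks"),
            f"annotation {ann['id']}")
        frames[f].views[c].append(
            Instance(np.asarray(ann["bbox"], float), kps, mask))
    return frames


# ---------------------------------------------------------------------------
# groupings + fitted states
# ---------------------------------------------------------------------------

def write_grouping(grouping: IdentityGrouping, frame: int, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "frame": frame,
               "groups": [[{"view": c, "instance": q} for c, q in g]
                          for g in grouping.groups],
               "junk": [{"view": c, "instance": q}
                        for c, q in grouping.junk]}
    Path(path).write_text(json.dumps(payload))


def read_grouping(path) -> tuple[IdentityGrouping, int]:
    d = json.loads(Path(path).read_text())
    groups = [[(n["view"], n["instance"]) for n in g] for g in d["groups"]]
    junk = [(n["view"], n["instance"]) for n in d["junk"]]
    return IdentityGrouping(groups, junk), d["frame"]


def write_fitted_states(states: list[list[FittedState]], out_dir,
                        keypoint_names: list[str] | None = None) -> None:
    """Pose JSON + keypoint CSV (frame, id, name, x, y, z, n_views_seen)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    poses = []
    with open(out_dir / "keypoints.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "id", "name", "x", "y", "z", "n_views_seen"])
        for frame_states in states:
            for st in frame_states:
                poses.append({
                    "frame": st.frame, "id": st.identity,
                    "theta": st.pose.theta.tolist(),
                    "scale": st.pose.scale,
                    "rot": st.pose.global_rot.tolist(),
                    "trans": st.pose.trans.tolist(),
                    "broken": st.broken})
                for m, kp in enumerate(st.keypoints):
                    name = (keypoint_names[m] if keypoint_names
                            else f"kp_{m}")
                    wr.writerow([st.frame, st.identity, name,
                                 *[repr(float(v)) for v in kp],
                                 int(st.n_views_seen[m])])
    (out_dir / "poses.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "poses": poses}))


def read_fitted_states(out_dir) -> list[dict]:
    return json.loads((Path(out_dir) / "poses.json").read_text())["poses"]


def write_manifest(path, config: dict, seed: int) -> None:
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {"schema_version": SCHEMA_VERSION,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
                "seed": seed, "version": __version__,
                "config": json.loads(blob)}
    Path(path).write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def mpjpe(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Mean per-joint position error (meters), NaN predictions excluded."""
    predicted = np.asarray(predicted, float)
    reference = np.asarray(reference, float)
    d = np.linalg.norm(predicted - reference, axis=-1)
    return float(np.nanmean(d))
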