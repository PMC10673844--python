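# meshmocap

Markerless 3D surface motion capture for multiple freely interacting
animals, from synchronized multi-view 2D detections. Instead of
triangulating keypoints independently — which fails exactly when animals
occlude each other — the pipeline fits an articulated surface mesh to all
available 2D evidence, so every keypoint is reported every frame, visible
or not, and the full body surface is available for downstream behavior
analysis (surface-to-surface contact, posture clustering, tail kinematics).

Intended users: labs doing quantitative behavior work on mid-size mammals
(pigs, dogs, rodents) with a calibrated multi-camera rig and an upstream 2D
detector producing per-view bounding boxes, keypoints and silhouettes.

## The model and the pipeline

The animal is an articulated mesh: template vertices `T̄` and joints `J̄`,
sparse row-stochastic skinning weights `W`, per-joint axis-angle rotations
`θ`, and a global similarity transform, so the posed surface is

    V = M(Θ) = s · R(r) · LBS(θ; T̄, J̄, W) + t,      X = J V

with `r = [r_z, r_y, r_x]` (z-y-x Euler), scale `s`, translation `t`, and a
sparse row-stochastic regressor `J` mapping vertices to the N_K named 3D
keypoints `X`. Three stages run per sequence:

1. **Cross-view association.** At the first frame, unordered detections
   become nodes of a multipartite graph weighted by mean epipolar distance
   of shared keypoints; identity groups are disjoint cliques selected to
   cover the most nodes at the lowest weight (an exhaustive oracle certifies
   the greedy solver on small instances). Later frames track identities by
   per-view Hungarian assignment against the projected previous keypoints.
2. **Mesh fitting.** Per individual, a damped least-squares (LM) loop
   minimizes `E = w_2D E_2D + w_sil E_sil + w_temp E_temp + w_reg E_reg +
   w_anchor E_anchor + w_floor E_floor`: reprojection error of regressed
   keypoints, a rendered-vs-detected silhouette signed-distance term with
   z-buffer visibility, temporal smoothness, pose regularization, an anchor
   pose prior retrieved from a pose library at the first frame, and a floor
   penalty. Occluded cues are filtered using the depth ordering of the
   previously fitted surfaces.
3. **Behavior analytics.** Drinking/feeding from nose-to-scene geometry;
   dyadic social behaviors (Approach, Leave, Head–Head/Body/Limb/Tail,
   Mount) from head-to-surface distances, top-view convex-hull overlap and
   body pitch; posture discovery via 178-dim pose features → PCA → t-SNE →
   KDE → watershed; tail wagging via a signed tail angle and its Welch
   power spectral density.

A built-in synthetic rig (procedural quadruped, calibrated camera ring,
scripted motion, detector-style corruption) generates every input format
with exact ground truth, so the whole pipeline is testable offline. See
`docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Simulate two animals on a 10-camera ring, associate, fit the mesh, run the
triangulation baseline on the same cues, and score both against ground
truth:

```
meshmocap simulate --preset two_dogs --frames 5 --seed 7 --out demo/sim
meshmocap match --detections demo/sim/detections.json \
    --calibration demo/sim/calibration.yaml --n-individuals 2 \
    --out demo/grouping.json
meshmocap fit --detections demo/sim/detections.json \
    --calibration demo/sim/calibration.yaml \
    --model-mesh demo/sim/model.obj --model-skeleton demo/sim/skeleton.json \
    --n-individuals 2 --out demo/fit
meshmocap triangulate --detections demo/sim/detections.json \
    --calibration demo/sim/calibration.yaml --n-individuals 2 \
    --out demo/tri.csv
meshmocap evaluate --fitted demo/fit --triangulated demo/tri.csv \
    --truth demo/sim/truth.json --model-mesh demo/sim/model.obj \
    --model-skeleton demo/sim/skeleton.json --out demo/report.json
```

Output of the run above:

```
wrote fixtures for 2 individuals, 10 views, 5 frames to demo/sim
groups: [10, 10], junk: 0
fitted 5 frames x 2 individuals on 10 views
triangulated 5 frames to demo/tri.csv
{
 "fit_mpjpe_m": 0.001367133776381626,
 "fit_missing_fraction": 0.0,
 "tri_mpjpe_m": 0.0017028598247551489,
 "tri_missing_fraction": 0.0
}
```

Reading it: `match` grouped all 10 views' detections into two pure identity
groups with nothing discarded; the mesh fit reconstructs the 19 keypoints
of a 0.7 m animal to 1.4 mm mean per-joint position error (MPJPE) under
2 px detection noise and 10% dropout, slightly better than per-keypoint MLE
triangulation on the same cues (1.7 mm) — and unlike triangulation it
reports every keypoint (`fit_missing_fraction: 0`) even when occlusion or
dropout leaves a keypoint with fewer than two views. `fit --views 3`
re-runs fitting on a 3-camera subset; `behave` and `posture` consume the
fitted output for event detection and posture mapping.

The same `fit`/`evaluate` path accepts externally produced assets — a mesh
OBJ + skeleton JSON for another species, per-camera calibration, and
detection JSON from any 2D detector — so released datasets can be processed
by pointing the flags at the downloaded files; nothing in the pipeline is
specific to the synthetic rig.

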