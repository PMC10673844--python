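# Methods

## The model

An animal is represented by an articulated triangle mesh. The template
surface `T̄` (N_V vertices) and template joints `J̄` (N_J joints, one root,
parents topologically sorted) are deformed by linear blend skinning: each
joint `i` carries an axis-angle rotation `φ_i`, world transforms compose
along the parent chain as

    G_i = G_parent(i) · T(J̄_i) · Rot(φ_i) · T(−J̄_i),

and a sparse row-stochastic skinning matrix `W` blends the per-joint rigid
transforms into vertex positions. On top sit four global parameters — an
isotropic scale `s`, a z-y-x Euler rotation `r = [r_z, r_y, r_x]` and a
translation `t` — so posed vertices are `V = s·R(r)·LBS(θ) + t`. Named 3D
keypoints are regressed from posed vertices by a second sparse
row-stochastic matrix `J`, `X = J·V`; keypoints anchored at joints are
approximated in the toy asset by the average of the nearest template
vertices to the joint. Units are meters, the world is z-up with the floor at
z = 0, and `R = R_z(r_z)·R_y(r_y)·R_x(r_x)` (intrinsic, applied in that
order) — the Euler convention is fixed here and used consistently by the
fitting code. The LBS variant is standard rigid-bone skinning; no dual
quaternions. The skinning accumulator adds `w_ij·((G_j − I)·v)` to the
template position so that the rest pose reproduces the template bit-exactly.

The pose splits into a local part `Θ^l = {θ, t_z, r_x, r_y}` and a global
part `Θ^g = {t_x, t_y, r_z, s}`. `normalize_pose` zeroes the global part;
the original surface is then exactly a scaled z-rotation plus xy-translation
of the normalized one, which the posture features rely on.

## Pipeline

**Association (first frame).** Detected instances across views form a
multipartite graph; edge weights are the mean symmetric point-to-epipolar-
line distance over mutually visible keypoints (the "distance" formula is a
design choice: symmetric and comparable across camera pairs). Edges above a
cutoff (default 25 px) or without shared keypoints are omitted. Identity
groups are cliques spanning distinct views; the solver enumerates all
cliques of the thresholded graph and greedily selects disjoint ones, larger
cliques first, then lower mean weight, then lexicographic node order.
Because "minimize total weight" alone is degenerate (empty groups are free),
both the greedy solver and the exhaustive oracle optimize the same
lexicographic objective: maximize the number of grouped nodes, then minimize
the summed mean clique weight. The brute-force oracle enumerates per-view
assignments with branch-and-bound pruning (clique feasibility plus a
coverage bound) and is exact up to 16 nodes.

**Tracking (later frames).** The previous frame's regressed 3D keypoints are
projected into each view; a per-view Hungarian assignment on mean 2D
keypoint distance carries identities forward, gated at 50 px (configurable).

**Mesh fitting.** Per individual, the pose minimizes

    E = w_2D·E_2D + w_sil·E_sil + w_temp·E_temp + w_reg·E_reg
        + w_anchor·E_anchor + w_floor·E_floor

with defaults w_2D = 1, w_sil = 5e-5, w_reg = 0.01, w_floor = 100; at the
first frame w_temp = 0, w_anchor = 0.01, during tracking w_temp = 1,
w_anchor = 0; λ_h = 25 in the anchor height prior. `E_2D` is the
confidence-weighted squared pixel error of projected keypoints; `E_temp`
penalizes keypoint displacement against the previous frame; `E_reg = ‖θ‖²`;
`E_anchor = ‖Θ^l − Θ^l_p*‖² + λ_h Σ (X_z − X_z,p*)²`; `E_floor` is a
one-sided quadratic ramp on keypoints below z = 0. `E_sil` compares the
signed distance transforms of the rendered and detected silhouettes sampled
(bilinearly) at the projections of visible mesh vertices. Both SDFs are
negative inside, normalized by half the image diagonal and clipped to
[−1, 1]; since both share the convention, the residual is
convention-invariant.

Visibility comes from a software z-buffer: every individual is rasterized
into every view at a working resolution (default 1/8 of the camera
resolution), the combined map is the per-pixel minimum, and a vertex is
visible when the combined depth at its pixel is within δ_z = 1 cm of its own
depth. The same machinery drives occlusion-aware cue filtering during
tracking: keypoints whose identity is depth-occluded at their pixel are
dropped, and a silhouette is dropped when more than ρ_occ = 0.5 of its
rendered area is covered by closer individuals (δ_z and ρ_occ are not
externally prescribed; both are configurable).

The minimizer is a self-contained damped least-squares (LM) loop over the
active parameters: λ starts at 1e-3, ×10 on a rejected step, ×0.5 on an
accepted one; convergence at relative energy change < 1e-6; iteration caps
60 for initialization (silhouette term forced off for the first 5
iterations) and 5 for tracking. Scale is clamped to [0.5, 2] to exclude
degenerate shrink-to-point solutions. Jacobians are forward finite
differences for all terms rather than analytic chain-rule derivatives: with
~80 parameters and a residual evaluation that only skins the regressor
support (a few dozen vertices), numeric Jacobians cost milliseconds and
remove a large class of derivation bugs; the rendered SDF is additionally
non-smooth, so an analytic Jacobian would not cover it anyway. For the
silhouette term the rendered SDF and visibility set are frozen over short
render cycles (default 5 accepted steps) and refreshed between cycles; the
energy trace is therefore guaranteed non-increasing within each cycle, and
the per-cycle traces are what the invariant tests check. Multi-individual
coupling through shared renders is block-coordinate: individuals are
optimized in turn against renders refreshed per round, rather than through
one joint Jacobian.

**Anchor retrieval.** At the first frame each library entry keeps its local
part fixed while `Θ^g` is fitted to the keypoint term (8 heading restarts,
translation initialized from a DLT triangulation of the visible keypoints);
entries are scored by keypoint error plus, when silhouettes are present, a
Chamfer-style mean squared detected-SDF value at projected non-tail vertices
with weight 20. The retrieval silhouette weight (20) and the fitting
silhouette weight (5e-5) are different constants on purpose: one scales a
per-vertex mean Chamfer score, the other a per-vertex SDF-difference sum.
Because the library's `{t_z, r_x, r_y}` are kept and scale is positive, a
retrieved anchor can never place the animal below the floor or flying.

**Triangulation baseline.** Per keypoint: DLT initialization, then
Levenberg-Marquardt minimization of the summed squared reprojection errors
(σ-weighting optional, off by default since no weighting is prescribed).
The reported residual is the RMS reprojection error — the quantity the MLE
actually minimizes, which makes "MLE residual ≤ DLT residual" well-posed;
the mean of per-view error norms is not monotone in the optimized objective
and can tick up even on a strictly better point. Keypoints seen by fewer
than two views are reported missing; an optional residual cutoff can gate
acceptance (off by default, as no gate is prescribed).

**PnP calibration.** Extrinsics from ≥ 6 scene-point correspondences: DLT on
normalized coordinates (rank-checked), sign fixed by median depth,
orthogonalization by SVD, then LM refinement of reprojection error.
Distortion is 5-parameter Brown-Conrady; the synthetic rig uses zero
distortion, and distorted observations are undistorted before any epipolar
or triangulation math.

## Behavior analytics

Scene rules: drinking = nose within 0.12 m of the tap; feeding = nose inside
a half-open 0.62 × 0.7 × 0.2 m box. Dyadic rules on the ordered pair (A, B):
`d_h` is the minimum distance from A's head vertices (all vertices with part
label `head`; the head extent is not otherwise prescribed) to B's surface,
downsampled to 546 vertices by farthest-point sampling (deterministic,
seeded with vertex 0 plus one vertex per body part so no part disappears);
`o(A,B)` is the convex-hull IoU of the two downsampled clouds projected to
the ground plane; pitch is the fitted `r_y`. Behaviors at frame T over the
window [T−W, T+W], W = 12:

    Approach:  d_h(T−W) > 0.2  and d_h(T+W) < 0.05
    Leave:     d_h(T−W) < 0.05 and d_h(T+W) > 0.2
    Head-X:    d_h(T) < 0.05 with X = part of the closest B vertex
    Mount:     pitch(A) > 20° and o(A,B) > 0.15

evaluated literally every frame (no extra persistence requirement — the
rules are applied exactly as stated) with contiguous positive frames merged
into one event. All thresholds are strict inequalities; the tests toggle
them with ±1e-6 perturbations.

Posture features are 178-dimensional per frame from normalized poses: 19
keypoint positions (57), 17 keypoint velocities excluding ears (51; central
differences × frame rate, one-sided at the ends), tail-root and center
heights (2), body pitch `r_y` and roll `r_x` (2), and axis-angle rotations
of 22 joints (66). The 22 joints are configurable and default to the active
set minus the two most distal tail joints — a package choice, since no joint
list is prescribed. The map is PCA to 16 components, t-SNE to 2D
(perplexity 80, fixed seed, PCA init), both axes min-max normalized to
[0.05, 0.95], Gaussian KDE (bandwidth 0.03) on a 200×200 grid normalized to
[0, 1], and a watershed of the inverted density. Two standard guards against
watershed over-segmentation are applied: markers are the h-maxima of the
density (prominence ≥ 0.1 of the maximum), and adjacent basins are merged
afterwards when their shared boundary saddle exceeds 0.2 of the weaker
basin's peak density. At the small sample sizes used here t-SNE imprints
lobes and ripples inside a single posture cluster; saddle-persistence
merging removes those splits while leaving the near-zero-density valleys
between genuinely distinct postures untouched.

Tail angle: `θ = |arccos(a·b)|·sgn` with `a` the unit vector tail_1→tail_2,
`b` the unit vector tail_7→tail_8, and the sign positive when the tail tip
lies on the left of the plane through tail_1, tail_2 and the body center
(normal `(tail_2−tail_1) × (center−tail_1)`). A center exactly on the tail
axis leaves the side undefined and raises an error. The PSD is Welch's
method at fs = 25 Hz, nperseg = 200 (bins every 0.125 Hz), linear units;
wagging is declared in a 10-s window when the peak PSD exceeds 1.5.

## The synthetic rig

The rig emulates a cage filmed by a ring of inward-looking cameras (default
10 cameras, radius 2.2 m, height 1.8 m, 1920×1080, focal length = image
width, zero distortion, all looking at the arena center 0.3 m above the
floor). The animal is a procedural quadruped — ellipsoid torso, spherical
head/nose/ears, two-segment tube legs, an 8-joint tail chain — with 574
vertices, 28 joints (24 active: everything except the root, nose and ears),
19 keypoints and nearest-bone Gaussian-falloff skinning (3 nearest bones,
rows renormalized). Body length is ~0.7 m nose to tail root, so 7 cm is 10%
of body length. The pose library holds five procedural entries (standing,
walking keyframe, sitting, lying left/right), each lifted to satisfy the
floor constraint exactly. Motion scripts interpolate per-joint rotations
between library poses by slerp while following a constant-velocity ground
path; defaults keep speeds ≤ 0.3 m/s, consistent with 25 Hz tracking.

Detection corruption: Gaussian pixel noise (default 2 px), random visibility
dropout (default 10%), occlusion-driven dropout from the z-buffer depth
test, binary mask erosion, and per-view instance shuffling. Everything is
deterministic under the scenario seed — repeated runs produce byte-identical
detection files. The noise defaults are rig choices meant to challenge but
not break association; they are not measured detector statistics.

What the rig does *not* emulate: appearance (no photorealism, fur or
texture), detector-style structured errors (left/right swaps, hallucinated
instances), soft-tissue deformation beyond LBS, camera desynchronization and
rolling shutter, real lens distortion. Passing the synthetic suite therefore
demonstrates the correctness and robustness of the geometry, association and
optimization machinery under controlled noise — not detector-grade accuracy
on real video, which depends on trained 2D networks that are out of scope
here (detections are consumed from files).

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: single frames or
short sequences (≤ 10 frames), 10–20 seeds per experiment, rasterization at
1/8 resolution, posture discovery on 800 synthetic feature vectors. These
sizes are the package's chosen study conditions; the underlying code paths
are size-agnostic. Ties in clique selection and farthest-point sampling are
broken lexicographically for determinism. Degenerate inputs raise typed
errors rather than producing NaNs: empty masks, coincident camera centers,
< 6 PnP points, < 2 triangulation views, degenerate tail chains, theta shape
mismatches.

## Known limitations

- The greedy clique partitioner matches the exhaustive optimum on the
  geometric graphs the rig produces; adversarial weight constructions can in
  principle defeat the greedy choice (the oracle suite would catch it).
- The silhouette term uses frozen-render cycles rather than a differentiable
  renderer; with very bad initialization the silhouette gradient can vanish
  (non-overlapping silhouettes), which the keypoint term and warmup schedule
  are there to prevent.
- Identity recovery after a full, long tracking loss is out of scope (no
  appearance model); trajectories are flagged broken after a configurable
  gap and keep propagating on priors.
- The toy asset's keypoint regressor approximates joint-anchored keypoints
  by nearby surface vertices; absolute keypoint placement therefore differs
  from any specific released asset, while all within-package computations
  remain self-consistent.
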