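"""Silhouette SDFs, rendering/visibility, energy terms and LM pose fitting."""

import numpy as np
import pytest

from meshmocap.fitting import (AnchorPoseLibrary, EnergyWeights, FitSchedule,
                               baseline_triangulate, energy_2d, energy_priors,
                               energy_sil, filter_occluded_cues, fit_frame,
                               rasterize_depth, rasterize_mesh,
                               retrieve_anchor_pose, sdf_from_mask,
                               vertex_visibility)
from meshmocap.association import FrameDetections, Instance, IdentityGrouping
from meshmocap.geometry import CameraModel, project
from meshmocap.model_core import PoseParams, lbs_keypoints, lbs_pose
from meshmocap.rig import NoiseSpec, simulate_sequence


def zero_pose(model, **kw):
    return PoseParams(np.zeros((model.n_active, 3)), **kw)


def cues_for(model, pose, cameras):
    X = lbs_keypoints(model, pose)
    return {c: np.column_stack([project(cam, X), np.ones(X.shape[0])])
            for c, cam in enumerate(cameras)}


class TestSDF:
    def test_disk_center_value_analytic(self):
        mask = np.zeros((384, 384), bool)
        yy, xx = np.mgrid[:384, :384]
        mask[(yy - 192) ** 2 + (xx - 192) ** 2 <= 50 ** 2] = True
        sdf = sdf_from_mask(mask).values
        half_diag = 0.5 * np.hypot(384, 384)
        assert sdf[192, 192] == pytest.approx(-50 / half_diag,
                                              abs=1.5 / half_diag)
        boundary = np.abs(np.hypot(yy - 192, xx - 192) - 50) < 0.5
        assert np.abs(sdf[boundary]).max() < 1.5 / half_diag

    def test_full_foreground_nonpositive(self):
        sdf = sdf_from_mask(np.ones((32, 32), bool)).values
        assert (sdf <= 0).all()

    def test_complement_antisymmetry_interior(self):
        mask = np.zeros((64, 64), bool)
        mask[20:44, 16:48] = True
        a = sdf_from_mask(mask).values
        b = sdf_from_mask(~mask).values
        interior = mask.copy()
        interior[:1] = interior[-1:] = False
        # away from the exact boundary the two transforms differ by one pixel
        half_diag = 0.5 * np.hypot(64, 64)
        assert np.abs(a + b)[interior].max() <= 1.01 / half_diag

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            sdf_from_mask(np.zeros((16, 16), bool))


def sphere_mesh(center, radius, subdiv=2):
    from meshmocap.rig import _icosphere
    v, f = _icosphere(subdiv)
    return v * radius + np.asarray(center), f


class TestRasterization:
    def _cam(self, size=(256, 256), f=400.0):
        w, h = size
        K = np.array([[f, 0, w / 2], [0, f, h / 2], [0, 0, 1.0]])
        return CameraModel(K, np.eye(3), np.zeros(3), np.zeros(5), size)

    def test_sphere_silhouette_is_analytic_disk(self):
        cam = self._cam()
        v, f = sphere_mesh([0, 0, 2.0], 0.3, subdiv=3)
        depth = rasterize_mesh(cam, v, f)
        sil = np.isfinite(depth)
        yy, xx = np.mgrid[:256, :256]
        d = 2.0
        r_pix = 400.0 * 0.3 / np.sqrt(d * d - 0.3 ** 2)
        disk = np.hypot(yy - 128, xx - 128) <= r_pix
        iou = (sil & disk).sum() / (sil | disk).sum()
        assert iou > 0.98

    def test_occluded_sphere_combined_depth(self):
        cam = self._cam()
        front = lbs_surface = sphere_mesh([0, 0, 1.5], 0.3)
        back = sphere_mesh([0, 0, 3.0], 0.2)
        from meshmocap.model_core import PosedSurface
        surfs = [PosedSurface(back[0], None, None),
                 PosedSurface(front[0], None, None)]
        # same faces for both spheres
        rendered = rasterize_depth([cam], surfs, front[1], scale=1.0)[0]
        front_only = rasterize_mesh(cam, front[0], front[1])
        vis = np.isfinite(front_only)
        np.testing.assert_allclose(rendered["combined"][vis],
                                   front_only[vis], atol=1e-9)

    def test_empty_surface_list(self):
        cam = self._cam()
        rendered = rasterize_depth([cam], [], np.zeros((0, 3), int))[0]
        assert not np.isfinite(rendered["combined"]).any()
        assert rendered["silhouettes"] == []


class TestVisibility:
    def test_single_convex_body_front_vertices_visible(self):
        cam = CameraModel(
            np.array([[400.0, 0, 128], [0, 400.0, 128], [0, 0, 1]]),
            np.eye(3), np.zeros(3), np.zeros(5), (256, 256))
        v, f = sphere_mesh([0, 0, 2.0], 0.3)
        depth = rasterize_mesh(cam, v, f)
        pix, valid, d = project(cam, v, return_valid=True)
        vis = vertex_visibility(depth, depth, pix, d)
        front = np.where(v[:, 2] < 2.0 - 0.1)[0]     # camera-facing half
        assert set(front).issubset(set(vis))

    def test_fully_occluded_body_empty(self):
        cam = CameraModel(
            np.array([[400.0, 0, 128], [0, 400.0, 128], [0, 0, 1]]),
            np.eye(3), np.zeros(3), np.zeros(5), (256, 256))
        vf, ff = sphere_mesh([0, 0, 1.2], 0.4)
        vb, fb = sphere_mesh([0, 0, 3.0], 0.1)
        from meshmocap.model_core import PosedSurface
        rendered = rasterize_depth(
            [cam], [PosedSurface(vb, None, None),
                    PosedSurface(vf, None, None)], ff, 1.0)[0]
        pix, valid, d = project(cam, vb, return_valid=True)
        vis = vertex_visibility(rendered["own"][0], rendered["combined"],
                                pix, d)
        assert vis.size == 0

    @staticmethod
    def _ray_hits(origin, direction, tri_verts):
        """Möller-Trumbore intersection distances of one ray with all
        triangles (brute force, no acceleration structure)."""
        v0, v1, v2 = (tri_verts[:, 0], tri_verts[:, 1], tri_verts[:, 2])
        e1, e2 = v1 - v0, v2 - v0
        p = np.cross(direction, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = origin - v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = q @ direction * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        return t[hit]

    def test_matches_ray_cast_oracle(self):
        cam = CameraModel(
            np.array([[300.0, 0, 160], [0, 300.0, 120], [0, 0, 1]]),
            np.eye(3), np.zeros(3), np.zeros(5), (320, 240))
        va, fa = sphere_mesh([0.05, 0, 2.0], 0.25)    # front
        vb, fb = sphere_mesh([-0.15, 0, 3.0], 0.35)   # partially hidden
        from meshmocap.model_core import PosedSurface
        rendered = rasterize_depth(
            [cam], [PosedSurface(vb, None, None),
                    PosedSurface(va, None, None)], fa, 1.0)[0]
        pix, valid, d = project(cam, vb, return_valid=True)
        vis = set(vertex_visibility(rendered["own"][0],
                                    rendered["combined"], pix, d).tolist())
        all_v = np.vstack([va, vb])
        all_f = np.vstack([fa, fb + len(va)])
        tris = all_v[all_f]
        agree = total = 0
        for q in range(len(vb)):
            dist = np.linalg.norm(vb[q])
            direction = vb[q] / dist
            t_hits = self._ray_hits(np.zeros(3), direction, tris)
            nearest = t_hits.min() if t_hits.size else np.inf
            margin = dist - nearest
            if abs(margin) < 0.02:
                continue                              # boundary-ambiguous
            total += 1
            oracle_visible = margin < 0.02
            if (q in vis) == oracle_visible:
                agree += 1
        assert total > 50
        assert agree / total > 0.9


class TestOcclusionFilter:
    def _two_animal_scene(self, toy_model, camera_ring, apart):
        pa = zero_pose(toy_model)
        pb = zero_pose(toy_model, trans=np.array(apart))
        return lbs_pose(toy_model, pa), lbs_pose(toy_model, pb), pa, pb

    def test_separated_animals_noop(self, toy_model, camera_ring):
        sa, sb, pa, pb = self._two_animal_scene(
            toy_model, camera_ring, [0.0, 0.9, 0.0])
        rendered = rasterize_depth(camera_ring, [sa, sb],
                                   toy_model.faces, 0.125)
        kp = np.column_stack([project(camera_ring[0], sa.keypoints),
                              np.ones(19)])
        frame = FrameDetections(views={0: [Instance([0, 0, 1, 1], kp)]},
                                mask_scale=0.125)
        grouping = IdentityGrouping([[(0, 0)]], [])
        out = filter_occluded_cues(grouping, rendered, frame,
                                   det_scale=0.125)
        np.testing.assert_array_equal(out.views[0][0].keypoints, kp)

    def test_keypoint_behind_other_animal_dropped(self, toy_model,
                                                  camera_ring):
        # identity 0 directly behind identity 1 along camera 0's axis
        cam = camera_ring[0]
        axis = -cam.rotation[2]          # from target toward camera
        sa = lbs_pose(toy_model, zero_pose(toy_model))
        pb = zero_pose(toy_model, scale=1.6,
                       trans=0.55 * np.array([axis[0], axis[1], 0.0]))
        sb = lbs_pose(toy_model, pb)
        rendered = rasterize_depth([cam], [sa, sb], toy_model.faces, 0.25)
        kp = np.column_stack([project(cam, sa.keypoints), np.ones(19)])
        frame = FrameDetections(views={0: [Instance([0, 0, 1, 1], kp)]},
                                mask_scale=0.25)
        grouping = IdentityGrouping([[(0, 0)]], [])
        log = []
        out = filter_occluded_cues(grouping, rendered, frame,
                                   det_scale=0.25, log=log)
        dropped = (out.views[0][0].keypoints[:, 2] == 0).sum()
        assert dropped > 10
        assert any(e["kind"] == "keypoint" for e in log)

    def test_mostly_covered_silhouette_dropped(self, toy_model, camera_ring):
        cam = camera_ring[0]
        axis = -cam.rotation[2]
        sa = lbs_pose(toy_model, zero_pose(toy_model))
        pb = zero_pose(toy_model, scale=1.6,
                       trans=0.55 * np.array([axis[0], axis[1], 0.0]))
        sb = lbs_pose(toy_model, pb)
        rendered = rasterize_depth([cam], [sa, sb], toy_model.faces, 0.25)
        kp = np.column_stack([project(cam, sa.keypoints), np.ones(19)])
        mask = rendered[0]["silhouettes"][0]
        frame = FrameDetections(views={0: [Instance([0, 0, 1, 1], kp,
                                                    mask)]},
                                mask_scale=0.25)
        grouping = IdentityGrouping([[(0, 0)]], [])
        log = []
        out = filter_occluded_cues(grouping, rendered, frame, rho_occ=0.5,
                                   det_scale=0.25, log=log)
        assert out.views[0][0].mask is None
        assert any(e["kind"] == "silhouette" for e in log)
        # keypoints that survive the depth test stay visible
        assert (out.views[0][0].keypoints[:, 2] > 0).sum() >= 0


class TestEnergy2D:
    def test_zero_at_generating_pose(self, toy_model, camera_ring):
        pose = zero_pose(toy_model)
        cues = cues_for(toy_model, pose, camera_ring)
        assert energy_2d(toy_model, pose, cues, camera_ring) < 1e-12

    def test_all_invisible_zero(self, toy_model, camera_ring):
        pose = zero_pose(toy_model)
        cues = cues_for(toy_model, pose, camera_ring)
        for y in cues.values():
            y[:, 2] = 0.0
        shifted = zero_pose(toy_model, trans=np.array([0.3, 0, 0]))
        assert energy_2d(toy_model, shifted, cues, camera_ring) == 0.0

    def test_translation_matches_pinhole_first_order(self, toy_model):
        f, depth = 1000.0, 10.0
        K = np.array([[f, 0, 500], [0, f, 500], [0, 0, 1.0]])
        cam = CameraModel(K, np.eye(3), np.array([0, 0, depth]),
                          np.zeros(5), (1000, 1000))
        pose = zero_pose(toy_model)
        cues = cues_for(toy_model, pose, [cam])
        moved = zero_pose(toy_model, trans=np.array([0.1, 0.0, 0.0]))
        e = energy_2d(toy_model, moved, cues, [cam])
        depths = lbs_keypoints(toy_model, pose)[:, 2] + depth
        expected = np.sum((0.1 * f / depths) ** 2)
        assert e == pytest.approx(expected, rel=0.02)


class TestEnergySil:
    def test_identical_silhouettes_near_zero(self, toy_model, camera_ring):
        pose = zero_pose(toy_model)
        surf = lbs_pose(toy_model, pose)
        rendered = rasterize_depth(camera_ring[:2], [surf],
                                   toy_model.faces, 0.125)
        sdfs = {c: sdf_from_mask(rendered[c]["silhouettes"][0])
                for c in range(2)}
        e = energy_sil(toy_model, pose, sdfs, rendered, 0, camera_ring[:2])
        assert e < 1e-3

    def test_decreases_toward_detected_pose(self, toy_model, camera_ring):
        target = zero_pose(toy_model, trans=np.array([0.12, 0.0, 0.0]))
        surf_t = lbs_pose(toy_model, target)
        det = rasterize_depth(camera_ring[:3], [surf_t],
                              toy_model.faces, 0.125)
        sdfs = {c: sdf_from_mask(det[c]["silhouettes"][0]) for c in range(3)}
        energies = []
        for u in np.linspace(0.0, 1.0, 5):
            pose = zero_pose(toy_model,
                             trans=np.array([0.12 * u, 0.0, 0.0]))
            surf = lbs_pose(toy_model, pose)
            rendered = rasterize_depth(camera_ring[:3], [surf],
                                       toy_model.faces, 0.125)
            energies.append(energy_sil(toy_model, pose, sdfs, rendered, 0,
                                       camera_ring[:3]))
        assert all(np.diff(energies) < 0)

    def test_tail_exclusion_ignores_tail_pose(self, toy_model, camera_ring):
        pose = zero_pose(toy_model)
        surf = lbs_pose(toy_model, pose)
        rendered = rasterize_depth(camera_ring[:2], [surf],
                                   toy_model.faces, 0.125)
        sdfs = {c: sdf_from_mask(rendered[c]["silhouettes"][0])
                for c in range(2)}
        bent = zero_pose(toy_model)
        tail_rows = [i for i, j in enumerate(toy_model.active_joints)
                     if toy_model.joint_names[j].startswith("tail")]
        bent.theta[tail_rows] = [0, 0, 0.6]
        e_ref = energy_sil(toy_model, pose, sdfs, rendered, 0,
                           camera_ring[:2], exclude_tail=True)
        e_bent = energy_sil(toy_model, bent, sdfs, rendered, 0,
                            camera_ring[:2], exclude_tail=True)
        # tail vertices are excluded, so bending the tail barely moves it
        assert abs(e_bent - e_ref) < 1e-2


class TestEnergyPriors:
    def test_trivial_values(self, toy_model):
        pose = zero_pose(toy_model)
        w = EnergyWeights(w_temp=1.0, w_anchor=0.01)
        terms = energy_priors(pose, pose, pose, toy_model, w)
        assert terms["E_temp"] == 0.0
        assert terms["E_anchor"] == 0.0
        assert terms["E_reg"] == 0.0
        assert terms["E_floor"] == 0.0

    def test_floor_ramp_contribution(self, toy_model):
        pose = zero_pose(toy_model, trans=np.array([0.0, 0.0, -5.0]))
        w = EnergyWeights(w_temp=0.0, w_anchor=0.0)
        terms = energy_priors(pose, None, None, toy_model, w)
        X = lbs_keypoints(toy_model, pose)
        expected = np.sum(np.maximum(-X[:, 2], 0) ** 2)
        assert terms["E_floor"] == pytest.approx(expected, rel=1e-12)

    def test_missing_prerequisites_raise(self, toy_model):
        pose = zero_pose(toy_model)
        with pytest.raises(ValueError, match="E_temp"):
            energy_priors(pose, None, None, toy_model,
                          EnergyWeights(w_temp=1.0, w_anchor=0.0))
        with pytest.raises(ValueError, match="E_anchor"):
            energy_priors(pose, None, None, toy_model,
                          EnergyWeights(w_temp=0.0, w_anchor=0.01))


class TestRetrieval:
    def test_generative_recovery_of_entry_and_transform(
            self, toy_model, pose_library, camera_ring):
        rng = np.random.default_rng(21)
        entry = 3                                     # lying_left
        truth = pose_library.entries[entry].copy()
        truth.trans[0], truth.trans[1] = rng.uniform(-0.4, 0.4, 2)
        truth.global_rot[0] = rng.uniform(-np.pi, np.pi)
        cues = cues_for(toy_model, truth, camera_ring)
        p_idx, fitted, _ = retrieve_anchor_pose(
            pose_library, cues, camera_ring, toy_model)
        assert p_idx == entry
        assert np.linalg.norm(fitted.trans[:2] - truth.trans[:2]) < 0.01
        dr = (fitted.global_rot[0] - truth.global_rot[0] + np.pi) \
            % (2 * np.pi) - np.pi
        assert abs(dr) < 0.02

    def test_lying_preferred_over_standing(self, toy_model, pose_library,
                                           camera_ring):
        truth = pose_library.entries[3].copy()        # lying_left
        cues = cues_for(toy_model, truth, camera_ring)
        p_idx, _, _ = retrieve_anchor_pose(pose_library, cues, camera_ring,
                                           toy_model)
        assert pose_library.names[p_idx].startswith("lying")

    def test_anchor_keypoints_respect_floor(self, toy_model, pose_library,
                                            camera_ring):
        rng = np.random.default_rng(22)
        for entry in range(len(pose_library.entries)):
            truth = pose_library.entries[entry].copy()
            truth.trans[0], truth.trans[1] = rng.uniform(-0.3, 0.3, 2)
            truth.global_rot[0] = rng.uniform(0, 2 * np.pi)
            cues = cues_for(toy_model, truth, camera_ring)
            _, fitted, _ = retrieve_anchor_pose(pose_library, cues,
                                                camera_ring, toy_model)
            kp = lbs_keypoints(toy_model, fitted)
            assert kp[:, 2].min() >= -1e-6

    def test_empty_library_error(self, toy_model, camera_ring):
        with pytest.raises(ValueError, match="empty"):
            retrieve_anchor_pose(AnchorPoseLibrary([], [], []), {},
                                 camera_ring, toy_model)


class TestFitFrame:
    def test_noise_free_recovery_under_1mm(self, toy_model, camera_ring):
        rng = np.random.default_rng(23)
        truth = zero_pose(toy_model)
        truth.theta[:4] = rng.normal(0, 0.2, (4, 3))
        truth.trans = np.array([0.1, -0.2, 0.0])
        cues = cues_for(toy_model, truth, camera_ring)
        init = truth.copy()
        init.theta = init.theta + rng.normal(0, np.deg2rad(5),
                                             init.theta.shape)
        init.trans = init.trans + rng.normal(0, 0.05, 3)
        fitted, trace = fit_frame(toy_model, init, cues, camera_ring,
                                  EnergyWeights.for_init(), FitSchedule(),
                                  mode="init", anchor=init)
        mpjpe = np.linalg.norm(lbs_keypoints(toy_model, fitted)
                               - lbs_keypoints(toy_model, truth),
                               axis=1).mean()
        assert mpjpe < 1e-3

    def test_energy_trace_monotone_on_accepted_steps(self, toy_model,
                                                     camera_ring):
        rng = np.random.default_rng(24)
        truth = zero_pose(toy_model, trans=np.array([0.2, 0.1, 0.0]))
        cues = cues_for(toy_model, truth, camera_ring)
        init = zero_pose(toy_model)
        _, trace = fit_frame(toy_model, init, cues, camera_ring,
                             EnergyWeights.for_init(), FitSchedule(),
                             mode="init", anchor=init)
        for cycle in trace:
            assert all(np.diff(cycle) <= 1e-9)

    def test_floor_invariant_with_high_weight(self, toy_model, camera_ring):
        truth = zero_pose(toy_model)
        cues = cues_for(toy_model, truth, camera_ring)
        init = zero_pose(toy_model, trans=np.array([0, 0, -0.1]))
        fitted, _ = fit_frame(toy_model, init, cues, camera_ring,
                              EnergyWeights.for_init(), FitSchedule(),
                              mode="init", anchor=init)
        kp = lbs_keypoints(toy_model, fitted)
        assert kp[:, 2].min() > -1e-3

    def test_dropout_fit_beats_triangulation(self, four_pigs):
        rng = np.random.default_rng(25)
        diffs = []
        for seed in range(5):
            sim = simulate_sequence(
                type(four_pigs)(four_pigs.model, four_pigs.cameras,
                                four_pigs.library, four_pigs.scripts[:1],
                                seed=seed),
                1, NoiseSpec(keypoint_sigma=2.0, dropout_rate=0.6,
                             identity_shuffle=False))
            frame = sim["detections"][0]
            cues = {c: frame.views[c][0].keypoints for c in frame.views}
            gt = sim["keypoints3d"][0][0]
            init = sim["poses"][0][0].copy()
            fitted, _ = fit_frame(four_pigs.model, init, cues,
                                  four_pigs.cameras,
                                  EnergyWeights.for_init(), FitSchedule(),
                                  mode="init", anchor=init)
            fit_err = np.linalg.norm(
                lbs_keypoints(four_pigs.model, fitted) - gt, axis=1).mean()
            tri = baseline_triangulate(cues, four_pigs.cameras)
            tri_err = np.nanmean(np.linalg.norm(tri - gt, axis=1))
            diffs.append(tri_err - fit_err)
        assert np.median(diffs) > 0


class TestExtendedTerms:
    def test_e3d_pulls_pose_to_triangulated_targets(self, toy_model,
                                                    camera_ring):
        rng = np.random.default_rng(26)
        truth = zero_pose(toy_model)
        truth.theta[:3] = rng.normal(0, 0.15, (3, 3))
        target = lbs_keypoints(toy_model, truth)
        target[5] = np.nan                         # untriangulatable keypoint
        init = truth.copy()
        init.theta = init.theta + rng.normal(0, 0.05, init.theta.shape)
        w = EnergyWeights(w_2d=0.0, w_3d=1.0, w_temp=0.0, w_anchor=0.0,
                          w_reg=1e-4)
        fitted, _ = fit_frame(toy_model, init, {}, camera_ring, w,
                              FitSchedule(), mode="init",
                              target_keypoints3d=target)
        err = np.linalg.norm(lbs_keypoints(toy_model, fitted)
                             - lbs_keypoints(toy_model, truth), axis=1)
        finite = np.isfinite(target[:, 0])
        assert err[finite].mean() < 1e-3

    def test_e3d_requires_targets(self, toy_model, camera_ring):
        w = EnergyWeights(w_3d=1.0, w_temp=0.0, w_anchor=0.0)
        with pytest.raises(ValueError, match="E_3D"):
            fit_frame(toy_model, zero_pose(toy_model), {}, camera_ring, w,
                      FitSchedule(), mode="init")

    def test_silhouette_term_does_not_worsen_mask_iou(self):
        """Rendered-vs-true silhouette IoU with the SDF term enabled is no
        worse (median over seeds) than keypoint-only fitting."""
        from meshmocap.rig import NoiseSpec, scenario_preset, simulate_sequence
        schedule = FitSchedule(max_iter_init=30)
        ious = {"no_sil": [], "sil": []}
        for seed in range(3):
            sc = scenario_preset("four_pigs_cage", seed=seed)
            sc.scripts = sc.scripts[:1]
            sim = simulate_sequence(sc, 1,
                                    NoiseSpec(keypoint_sigma=4.0,
                                              dropout_rate=0.2,
                                              identity_shuffle=False),
                                    render_masks=True)
            frame = sim["detections"][0]
            cams = sc.cameras[:3]
            cues = {c: frame.views[c][0].keypoints for c in range(3)}
            sdfs = {c: sdf_from_mask(frame.views[c][0].mask)
                    for c in range(3)
                    if frame.views[c][0].mask is not None
                    and frame.views[c][0].mask.any()}
            init = sim["poses"][0][0].copy()
            rng = np.random.default_rng(seed)
            init.theta = init.theta + rng.normal(0, 0.1, init.theta.shape)
            init.trans = init.trans + rng.normal(0, 0.03, 3)

            def mask_iou(pose):
                surf = lbs_pose(sc.model, pose)
                rendered = rasterize_depth(cams, [surf], sc.model.faces,
                                           0.125)
                vals = []
                for c in range(3):
                    sil = rendered[c]["silhouettes"][0]
                    gtm = frame.views[c][0].mask
                    vals.append((sil & gtm).sum() / max((sil | gtm).sum(),
                                                        1))
                return float(np.mean(vals))

            pose_no, _ = fit_frame(sc.model, init, cues, cams,
                                   EnergyWeights.for_init(), schedule,
                                   mode="init", anchor=init)
            pose_sil, _ = fit_frame(sc.model, init, cues, cams,
                                    EnergyWeights.for_init(), schedule,
                                    mode="init", anchor=init,
                                    detected_sdfs=sdfs, sdf_scale=0.125)
            ious["no_sil"].append(mask_iou(pose_no))
            ious["sil"].append(mask_iou(pose_sil))
        assert (np.median(ious["sil"])
                >= np.median(ious["no_sil"]) - 0.01)


class TestRemovalLogging:
    def test_fit_sequence_logs_occlusion_removals(self):
        from meshmocap.fitting import fit_sequence
        from meshmocap.rig import (NoiseSpec, WalkScript, scenario_preset,
                                   simulate_sequence)
        sc = scenario_preset("two_dogs", seed=14)
        sc.scripts = [WalkScript(np.array([-0.3, 0.0]), np.pi / 2,
                                 speed=0.0),
                      WalkScript(np.array([0.45, 0.0]), np.pi / 2,
                                 speed=0.0)]
        sc.cameras = sc.cameras[:4]
        sim = simulate_sequence(sc, 2, NoiseSpec(keypoint_sigma=2.0,
                                                 dropout_rate=0.0,
                                                 identity_shuffle=False),
                                render_masks=True)
        removal_log: list = []
        # w_sil=0 keeps the fit keypoint-only while the occlusion filter
        # still runs on the rendered state and logs removals
        fit_sequence(sc.model, sim["detections"], sc.cameras, sc.library, 2,
                     weights_init=EnergyWeights.for_init(w_sil=0.0),
                     weights_track=EnergyWeights.for_tracking(w_sil=0.0),
                     use_silhouettes=True, removal_log=removal_log)
        assert removal_log
        assert all({"stage", "frame", "kind"} <= set(e)
                   for e in removal_log)
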