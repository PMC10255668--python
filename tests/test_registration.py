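"""Fiducial detection, PnP pose estimation and MI-based refinement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thermomesh.camera import CameraModel, ViewPose, project
from thermomesh.registration import (
    DegenerateMarkersError,
    MarkerObservation,
    detect_marker_blobs,
    estimate_pose_from_fiducials,
    match_blobs_to_markers,
    mutual_information,
    refine_pose,
    register_view,
)
from thermomesh.thermal_io import FRAME_SHAPE, ThermalFrame

TABLE_CAMERA = CameraModel(radial=(-0.1004, -1.0318))


def constant_frame(value=30.0):
    return ThermalFrame(values=np.full(FRAME_SHAPE, value), view_id="f")


class TestBlobDetection:
    def test_centroids_near_projected_marker_centres(self, scene_noiseless):
        """Well-facing markers are localized within a pixel of their
        projected cube centres (oracle: ground-truth pose projection)."""
        cam = scene_noiseless.camera
        n_checked = 0
        for pose, frame in zip(scene_noiseless.poses, scene_noiseless.frames["rest"]):
            blobs = detect_marker_blobs(frame)
            assert len(blobs) >= 3
            obs = match_blobs_to_markers(
                blobs, scene_noiseless.marker_centers,
                scene_noiseless.marker_normals, cam, pose,
            )
            assert len(obs) >= 3
            for o in obs:
                view_dir = pose.camera_center - o.mesh_point
                view_dir /= np.linalg.norm(view_dir)
                facing = scene_noiseless.marker_normals[o.marker_id] @ view_dir
                pred = project(cam, pose, o.mesh_point[None], strict=False)[0]
                err = np.linalg.norm(pred - o.image_point)
                assert err < 2.0
                if facing > 0.3:
                    assert err < 1.0
                    n_checked += 1
        assert n_checked >= 7

    def test_constant_frame_yields_no_blobs(self):
        assert len(detect_marker_blobs(constant_frame())) == 0

    def test_merged_markers_give_single_centroid(self):
        values = np.full(FRAME_SHAPE, 31.0)
        values[100:104, 100:110] = 26.0  # two cubes touching = one component
        blobs = detect_marker_blobs(ThermalFrame(values=values, view_id="f"))
        assert len(blobs) == 1

    def test_small_components_discarded(self):
        values = np.full(FRAME_SHAPE, 31.0)
        values[50, 50] = 26.0  # 1 px: below the minimum size
        assert len(detect_marker_blobs(ThermalFrame(values=values, view_id="f"))) == 0


class TestPoseEstimation:
    def make_obs(self, points, pose, camera, noise=0.0, rng=None):
        uv = project(camera, pose, points, strict=False)
        if noise and rng is not None:
            uv = uv + rng.normal(0.0, noise, uv.shape)
        return [MarkerObservation(k, uv[k], points[k]) for k in range(len(points))]

    def test_noiseless_recovery_multistart(self, scene_noiseless):
        truth = scene_noiseless.poses[1]
        obs = self.make_obs(scene_noiseless.marker_centers, truth, TABLE_CAMERA)
        pose, rmse = estimate_pose_from_fiducials(obs, TABLE_CAMERA)
        rot_err = np.rad2deg(
            np.linalg.norm(Rotation.from_matrix(pose.rotation @ truth.rotation.T).as_rotvec())
        )
        trans_err = np.linalg.norm(pose.translation - truth.translation)
        assert rot_err < 0.01
        assert trans_err < 1e-4  # 0.1 mm
        assert rmse < 1e-6

    def test_collinear_markers_rejected(self):
        pts = np.array([[0.0, 0.0, z] for z in (0.0, 0.05, 0.10)])
        obs = [MarkerObservation(k, np.array([100.0, 100.0 + 20 * k]), pts[k]) for k in range(3)]
        with pytest.raises(DegenerateMarkersError):
            estimate_pose_from_fiducials(obs, TABLE_CAMERA)

    def test_two_markers_rejected(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.05, 0.0, 0.0]])
        obs = [MarkerObservation(k, np.array([100.0, 100.0]), pts[k]) for k in range(2)]
        with pytest.raises(DegenerateMarkersError):
            estimate_pose_from_fiducials(obs, TABLE_CAMERA)

    def test_noise_bounds_from_monte_carlo_oracle(self, scene_noiseless):
        """1 px centroid noise, 4 markers at 120 cm: reprojection stays at
        the pixel level and the platform prior keeps the camera centre
        within a few centimetres (in-plane translation is degenerate with
        rotation for a shallow constellation, so millimetre-level absolute
        pose recovery is not attainable from 4 points alone)."""
        truth = scene_noiseless.poses[0]
        pts = scene_noiseless.marker_centers[:4]
        uv_true = project(TABLE_CAMERA, truth, pts, strict=False)
        reproj, center = [], []
        for s in range(40):
            rng = np.random.default_rng(s)
            obs = [
                MarkerObservation(k, uv_true[k] + rng.normal(0, 1, 2), pts[k])
                for k in range(4)
            ]
            pose, rmse = estimate_pose_from_fiducials(
                obs, TABLE_CAMERA, initial_pose=truth, center_prior_sigma=0.02
            )
            uv_est = project(TABLE_CAMERA, pose, pts, strict=False)
            reproj.append(np.sqrt(np.mean(np.sum((uv_est - uv_true) ** 2, axis=1))))
            center.append(np.linalg.norm(pose.camera_center - truth.camera_center))
        assert np.median(reproj) < 2.0      # px
        assert np.median(center) < 0.030    # m

    def test_equivariance_under_rigid_transform(self, scene_noiseless, rng):
        truth = scene_noiseless.poses[2]
        pts = scene_noiseless.marker_centers
        obs = self.make_obs(pts, truth, TABLE_CAMERA)
        pose_a, _ = estimate_pose_from_fiducials(obs, TABLE_CAMERA)

        r0 = Rotation.from_rotvec(rng.normal(0, 0.5, 3)).as_matrix()
        t0 = rng.normal(0, 0.2, 3)
        pts_b = pts @ r0.T + t0
        obs_b = [MarkerObservation(k, obs[k].image_point, pts_b[k]) for k in range(len(pts))]
        pose_b, _ = estimate_pose_from_fiducials(obs_b, TABLE_CAMERA)

        # world' -> camera must equal (world -> camera) o (world' -> world)
        np.testing.assert_allclose(pose_b.rotation, pose_a.rotation @ r0.T, atol=1e-5)
        np.testing.assert_allclose(
            pose_b.translation, pose_a.translation - pose_a.rotation @ r0.T @ t0, atol=1e-5
        )


class TestMutualInformation:
    def test_identical_images_give_marginal_entropy(self, rng):
        img = rng.uniform(0, 1, (100, 100))
        mi = mutual_information(img, img, bins=32)
        hist, _ = np.histogram(img, bins=32)
        p = hist / hist.sum()
        h = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mi == pytest.approx(h, abs=1e-12)

    def test_independent_noise_mi_near_zero(self, rng):
        # Sampling bias is ~(B-1)^2 / (2 N ln 2); 16 bins at 1e4 samples
        # keeps it well under the 0.05-bit budget.
        a = rng.uniform(0, 1, (100, 100))
        b = rng.uniform(0, 1, (100, 100))
        assert mutual_information(a, b, bins=16) <= 0.05

    def test_invariant_under_bijective_relabeling(self, rng):
        a = rng.integers(0, 8, (80, 80)).astype(float)
        b = rng.integers(0, 8, (80, 80)).astype(float)
        # v -> v^2 is bijective on {0..7}; 50 equal-width bins keep each
        # relabeled value in its own bin.
        mi_1 = mutual_information(a, b, bins=50)
        mi_2 = mutual_information(a, b**2, bins=50)
        assert mi_1 == pytest.approx(mi_2, abs=1e-12)

    def test_symmetric_and_nonnegative(self, rng):
        a = rng.normal(0, 1, (50, 50))
        b = a + rng.normal(0, 0.5, (50, 50))
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a), abs=1e-12)
        assert mutual_information(a, b) >= 0.0

    def test_empty_mask_rejected(self, rng):
        a = rng.normal(0, 1, (10, 10))
        with pytest.raises(ValueError):
            mutual_information(a, a, mask=np.zeros((10, 10), dtype=bool))


class TestRefinement:
    def test_ground_truth_init_not_worsened(self, scene_noiseless):
        truth = scene_noiseless.poses[1]
        frame = scene_noiseless.frames["rest"][1]
        res = refine_pose(truth, frame, scene_noiseless.mesh, scene_noiseless.camera)
        assert res.mi_score >= res.mi_initial - 1e-12
        uv_t = project(scene_noiseless.camera, truth, scene_noiseless.marker_centers, strict=False)
        uv_r = project(scene_noiseless.camera, res.pose, scene_noiseless.marker_centers, strict=False)
        assert np.sqrt(np.mean(np.sum((uv_t - uv_r) ** 2, axis=1))) < 0.5

    def test_perturbed_init_improves_marker_reprojection(self, scene_noiseless):
        truth = scene_noiseless.poses[3]
        frame = scene_noiseless.frames["rest"][3]
        perturbed = truth.compose_delta(np.deg2rad([2.0, 0.0, 0.0]), [0.005, 0.0, 0.0])

        def marker_rmse(p):
            uv_t = project(scene_noiseless.camera, truth, scene_noiseless.marker_centers, strict=False)
            uv_p = project(scene_noiseless.camera, p, scene_noiseless.marker_centers, strict=False)
            return np.sqrt(np.mean(np.sum((uv_t - uv_p) ** 2, axis=1)))

        before = marker_rmse(perturbed)
        res = refine_pose(perturbed, frame, scene_noiseless.mesh, scene_noiseless.camera)
        assert marker_rmse(res.pose) < before
        assert res.mi_score >= res.mi_initial

    def test_large_perturbation_is_documented_local_optimum(self, scene_noiseless):
        truth = scene_noiseless.poses[0]
        frame = scene_noiseless.frames["rest"][0]
        far = truth.compose_delta([0.0, 0.0, np.pi / 2], [0.0, 0.0, 0.0])
        res = refine_pose(far, frame, scene_noiseless.mesh, scene_noiseless.camera,
                          max_evals=60)
        # Refinement cannot cross a 90-degree basin; it must not pretend to.
        rot_err = np.rad2deg(np.linalg.norm(
            Rotation.from_matrix(res.pose.rotation @ truth.rotation.T).as_rotvec()
        ))
        assert rot_err > 45.0


class TestEndToEnd:
    def test_marker_positions_implied_by_recovered_poses(self, scene_noiseless):
        """Median marker displacement implied by the recovered poses stays
        below 3 mm (pixel error converted at the 120 cm working distance)."""
        cam = scene_noiseless.camera
        mm_per_px = 1.2 / np.mean(cam.focal) * 1000.0
        displacements = []
        for pose, frame in zip(scene_noiseless.poses, scene_noiseless.frames["rest"]):
            res = register_view(
                frame, scene_noiseless.mesh, scene_noiseless.marker_centers,
                scene_noiseless.marker_normals, cam, pose,
            )
            uv_t = project(cam, pose, scene_noiseless.marker_centers, strict=False)
            uv_r = project(cam, res.pose, scene_noiseless.marker_centers, strict=False)
            displacements.extend(np.linalg.norm(uv_r - uv_t, axis=1) * mm_per_px)
        assert np.median(displacements) <= 3.0
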