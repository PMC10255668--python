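"""Visibility, per-vertex colour transfer, decoding, and mesh clean-up."""

import numpy as np
import pytest
import trimesh

from thermomesh.camera import CameraModel, look_at_pose
from thermomesh.colormap import encode_temperatures
from thermomesh.mesh import LimbMesh, SENTINEL_RGB
from thermomesh.texturing import (
    assign_vertex_colors,
    bilinear_sample,
    clean_mesh,
    colors_to_temperatures,
    compute_visibility,
    decimate_vertex_clustering,
)

CAMERA = CameraModel(radial=(-0.1004, -1.0318))


@pytest.fixture(scope="module")
def sphere_mesh():
    tm = trimesh.creation.icosphere(subdivisions=4, radius=0.05)
    return LimbMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="module")
def front_pose():
    return look_at_pose([1.2, 0.0, 0.0], [0.0, 0.0, 0.0])


class TestVisibility:
    def test_front_facing_vertex_visible_with_high_weight(self, sphere_mesh, front_pose):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose])
        front = np.argmax(sphere_mesh.vertices[:, 0])
        assert asg.visible[0, front]
        assert asg.weights[0, front] > 0.95

    def test_back_facing_vertex_invisible(self, sphere_mesh, front_pose):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose])
        back = np.argmin(sphere_mesh.vertices[:, 0])
        assert not asg.visible[0, back]
        assert asg.weights[0, back] == 0.0

    def test_weight_zero_iff_invisible(self, sphere_mesh, front_pose):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose])
        np.testing.assert_array_equal(asg.visible[0], asg.weights[0] > 0)

    def test_occlusion_agrees_with_ray_cast_oracle(self, scene_noiseless, rng):
        """Occluded-by-cube vertices match an independent ray-triangle test."""
        mesh = scene_noiseless.mesh
        pose = scene_noiseless.poses[0]
        asg = compute_visibility(mesh, CAMERA, [pose])
        origin = pose.camera_center
        tri = mesh.vertices[mesh.faces]
        # Sample skin vertices facing the camera; verify the z-buffer
        # verdict against exhaustive Moeller-Trumbore occlusion.
        facing = asg.weights[0] > 0.4
        idx = rng.choice(np.flatnonzero(facing), size=60, replace=False)
        agree = 0
        for i in idx:
            v = mesh.vertices[i]
            d = v - origin
            dist = np.linalg.norm(d)
            d = d / dist
            e1 = tri[:, 1] - tri[:, 0]
            e2 = tri[:, 2] - tri[:, 0]
            pvec = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, pvec)
            ok = np.abs(det) > 1e-14
            inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            tvec = origin - tri[:, 0]
            bu = np.einsum("ij,ij->i", tvec, pvec) * inv
            qvec = np.cross(tvec, e1)
            bv = np.einsum("j,ij->i", d, qvec) * inv
            tdist = np.einsum("ij,ij->i", e2, qvec) * inv
            hit = ok & (bu >= 0) & (bv >= 0) & (bu + bv <= 1) & (tdist > 1e-6)
            occluded_oracle = np.any(tdist[hit] < dist - 1e-4)
            if occluded_oracle == (not asg.visible[0, i]):
                agree += 1
        assert agree >= 57  # > 95% agreement; boundary pixels may differ


class TestColorAssignment:
    def test_single_view_constant_image(self, sphere_mesh, front_pose):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose])
        img = np.full((240, 320, 3), (10, 200, 30), dtype=np.uint8)
        out = assign_vertex_colors(sphere_mesh, [img], asg, blend=False)
        vis = asg.visible[0]
        assert np.all(out.vertex_rgb[vis] == (10, 200, 30))
        assert np.all(out.vertex_rgb[~vis] == SENTINEL_RGB)

    def test_equal_weight_blend_is_channel_mean(self, sphere_mesh, front_pose):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose, front_pose])
        img_a = np.full((240, 320, 3), (100, 0, 0), dtype=np.uint8)
        img_b = np.full((240, 320, 3), (0, 0, 200), dtype=np.uint8)
        out = assign_vertex_colors(sphere_mesh, [img_a, img_b], asg, blend=True)
        vis = asg.visible.all(axis=0)
        assert np.all(out.vertex_rgb[vis] == (50, 0, 100))

    def test_no_blend_colour_is_resampled_best_view(self, scene_noiseless):
        """Colour conservation: with blending off every vertex colour equals
        a fresh bilinear sample of its best view's image."""
        mesh = scene_noiseless.mesh
        images = [
            encode_temperatures(f.values)
            for f in scene_noiseless.frames["rest"]
        ]
        asg = compute_visibility(mesh, scene_noiseless.camera, scene_noiseless.poses)
        out = assign_vertex_colors(mesh, images, asg, blend=False)
        check = np.flatnonzero(asg.best_view >= 0)[::50]
        for i in check:
            k = asg.best_view[i]
            expected = bilinear_sample(
                images[k], asg.pixels[k, [i]], asg.neighbor_ok[k, [i]]
            )[0]
            assert np.all(np.abs(out.vertex_rgb[i].astype(float) - expected) <= 0.5 + 1e-9)

    def test_too_many_frames_rejected(self, sphere_mesh, front_pose):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose] * 11)
        imgs = [np.zeros((240, 320, 3), dtype=np.uint8)] * 11
        with pytest.raises(ValueError):
            assign_vertex_colors(sphere_mesh, imgs, asg)


class TestDecoding:
    def test_constant_encoded_colour_decodes_to_temperature(
        self, sphere_mesh, front_pose, ramp_model
    ):
        asg = compute_visibility(sphere_mesh, CAMERA, [front_pose])
        rgb = encode_temperatures(np.array(31.0))
        img = np.full((240, 320, 3), rgb, dtype=np.uint8)
        colored = assign_vertex_colors(sphere_mesh, [img], asg, blend=True)
        out = colors_to_temperatures(colored, ramp_model)
        vis = asg.visible[0]
        np.testing.assert_allclose(out.vertex_temperature[vis], 31.0, atol=0.04)
        assert np.all(np.isnan(out.vertex_temperature[~vis]))

    def test_missing_colours_rejected(self, sphere_mesh, ramp_model):
        with pytest.raises(ValueError):
            colors_to_temperatures(sphere_mesh, ramp_model)

    def test_blended_seam_colours_decode_finite_in_span(self, scene_noiseless, ramp_model):
        images = [encode_temperatures(f.values) for f in scene_noiseless.frames["post_walk"]]
        asg = compute_visibility(scene_noiseless.mesh, scene_noiseless.camera, scene_noiseless.poses)
        colored = assign_vertex_colors(scene_noiseless.mesh, images, asg, blend=True)
        out = colors_to_temperatures(colored, ramp_model)
        t = out.vertex_temperature
        finite = np.isfinite(t)
        assert finite.sum() > 0.8 * len(t)
        assert np.all(t[finite] >= 28.0) and np.all(t[finite] <= 37.0)

    def test_ground_truth_recovery_single_view_vertices(self, scene_noiseless, ramp_model):
        """Noiseless renders: single-view skin vertices recovered to 0.1 degC."""
        mesh = scene_noiseless.mesh
        images = [encode_temperatures(f.values) for f in scene_noiseless.frames["rest"]]
        asg = compute_visibility(mesh, scene_noiseless.camera, scene_noiseless.poses)
        out = colors_to_temperatures(
            assign_vertex_colors(mesh, images, asg, blend=True), ramp_model
        )
        gt = np.clip(scene_noiseless.temperatures["rest"], 28.0, 37.0)
        skin = mesh.marker_id < 0
        single = asg.visible.sum(axis=0) == 1
        sel = np.isfinite(out.vertex_temperature) & skin & single
        assert sel.sum() > 500
        rmse = np.sqrt(np.mean((out.vertex_temperature[sel] - gt[sel]) ** 2))
        assert rmse <= 0.1


class TestCleanMesh:
    def test_large_sphere_decimated_to_target_with_genus_preserved(self):
        tm = trimesh.creation.uv_sphere(count=(700, 702))
        assert len(tm.vertices) > 4.8e5
        v, f = decimate_vertex_clustering(
            np.asarray(tm.vertices), np.asarray(tm.faces), 16000
        )
        assert 0.9 * 16000 <= len(v) <= 1.1 * 16000
        out = trimesh.Trimesh(v, f, process=False)
        assert out.euler_number == 2  # genus 0 preserved

    def test_decimation_error_bounded_by_edge_length(self):
        tm = trimesh.creation.icosphere(subdivisions=5, radius=0.05)
        v, f = decimate_vertex_clustering(np.asarray(tm.vertices), np.asarray(tm.faces), 2000)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(v).query(np.asarray(tm.vertices))
        mean_edge = trimesh.Trimesh(v, f, process=False).edges_unique_length.mean()
        assert d.max() <= 2.0 * mean_edge

    def test_small_clean_mesh_unchanged(self):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=0.05)
        out = clean_mesh(LimbMesh(np.asarray(tm.vertices), np.asarray(tm.faces)),
                         target_vertices=16000, remove_interior=False)
        assert out.n_vertices == len(tm.vertices)

    def test_largest_component_kept(self):
        limb = trimesh.creation.icosphere(subdivisions=4, radius=0.05)
        floor = trimesh.creation.box(extents=[0.02, 0.02, 0.002])
        floor.apply_translation([0.3, 0.0, 0.0])
        merged = trimesh.util.concatenate([limb, floor])
        out = clean_mesh(LimbMesh(np.asarray(merged.vertices), np.asarray(merged.faces)),
                         target_vertices=16000, remove_interior=False)
        assert out.n_vertices == len(limb.vertices)

    def test_interior_geometry_removed(self):
        outer = trimesh.creation.icosphere(subdivisions=4, radius=0.05)
        # A blob fully inside the sphere: invisible from every direction,
        # attached to nothing.
        inner = trimesh.creation.icosphere(subdivisions=2, radius=0.01)
        merged = trimesh.util.concatenate([outer, inner])
        out = clean_mesh(LimbMesh(np.asarray(merged.vertices), np.asarray(merged.faces)),
                         target_vertices=16000)
        assert out.n_vertices == len(outer.vertices)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            clean_mesh(LimbMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int)),
                       target_vertices=100)
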