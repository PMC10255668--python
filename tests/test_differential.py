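"""Differential maps, marker-halo statistics and hot-spot summaries."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from thermomesh.differential import (
    DifferentialMap,
    RegistrationErrorStats,
    differential_map,
    marker_halo_error,
    summarize_hotspots,
)
from thermomesh.mesh import LimbMesh


@pytest.fixture()
def sphere_pair():
    tm = trimesh.creation.icosphere(subdivisions=3, radius=0.05)
    mesh = LimbMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    a, b = mesh.copy(), mesh.copy()
    a.vertex_temperature = np.full(mesh.n_vertices, 34.0)
    b.vertex_temperature = np.full(mesh.n_vertices, 31.0)
    return a, b


class TestDifferentialMap:
    def test_walk_minus_rest(self, sphere_pair):
        a, b = sphere_pair
        diff = differential_map(a, b)
        np.testing.assert_allclose(diff.delta_t, 3.0)

    def test_antisymmetry_exact(self, sphere_pair, rng):
        a, b = sphere_pair
        a.vertex_temperature = rng.uniform(28, 37, a.n_vertices)
        b.vertex_temperature = rng.uniform(28, 37, b.n_vertices)
        d_ab = differential_map(a, b).delta_t
        d_ba = differential_map(b, a).delta_t
        np.testing.assert_array_equal(d_ab, -d_ba)

    def test_missing_vertices_propagate(self, sphere_pair):
        a, b = sphere_pair
        a.vertex_temperature[7] = np.nan
        diff = differential_map(a, b)
        assert np.isnan(diff.delta_t[7])
        assert np.isfinite(diff.delta_t[8])

    def test_vertex_count_mismatch_rejected(self, sphere_pair):
        a, b = sphere_pair
        tm = trimesh.creation.icosphere(subdivisions=2)
        small = LimbMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        small.vertex_temperature = np.full(small.n_vertices, 30.0)
        with pytest.raises(ValueError):
            differential_map(a, small)

    def test_extremes_get_first_and_last_jet_colour(self, sphere_pair, rng):
        a, b = sphere_pair
        a.vertex_temperature = 31.0 + rng.uniform(0.0, 3.0, a.n_vertices)
        a.vertex_temperature[3] = 31.0   # dT 0 = minimum
        a.vertex_temperature[5] = 35.0   # dT 4 = maximum
        diff = differential_map(a, b)
        assert tuple(diff.colors[np.argmin(diff.delta_t)]) == (0, 0, 128)
        assert tuple(diff.colors[np.argmax(diff.delta_t)]) == (128, 0, 0)


class TestMarkerHalo:
    def make_diff(self, delta):
        tm = trimesh.creation.icosphere(subdivisions=4, radius=0.05)
        mesh = LimbMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        colors = np.zeros((mesh.n_vertices, 3), dtype=np.uint8)
        return DifferentialMap(mesh=mesh, delta_t=delta, colors=colors)

    def test_coincident_halo_gives_zero_distance(self):
        tm = trimesh.creation.icosphere(subdivisions=4, radius=0.05)
        verts = np.asarray(tm.vertices)
        center = np.array([0.05, 0.0, 0.0])
        delta = np.full(len(verts), 2.0)
        near = np.linalg.norm(verts - center, axis=1) < 0.008
        delta[near] = 0.0
        diff = self.make_diff(delta)
        stats = marker_halo_error(diff, center[None, :], np.array([[1.0, 0.0, 0.0]]))
        assert stats.per_marker[0] == pytest.approx(0.0, abs=0.2)

    def test_displaced_halo_measures_offset(self):
        tm = trimesh.creation.icosphere(subdivisions=4, radius=0.05)
        verts = np.asarray(tm.vertices)
        center = np.array([0.05, 0.0, 0.0])
        shifted = np.array([0.0498, 0.004, 0.0])  # ~4 mm along the surface
        delta = np.full(len(verts), 2.0)
        delta[np.linalg.norm(verts - shifted, axis=1) < 0.006] = 0.0
        diff = self.make_diff(delta)
        stats = marker_halo_error(diff, center[None, :], np.array([[1.0, 0.0, 0.0]]))
        assert stats.per_marker[0] == pytest.approx(4.0, abs=1.0)

    def test_order_statistics_against_sorting_oracle(self):
        distances = [0.0, 1.0, 2.7, 2.7, 3.5, 4.0, 5.0]
        stats = RegistrationErrorStats(per_marker=distances)
        assert stats.median == pytest.approx(np.sort(distances)[len(distances) // 2])
        assert stats.median == pytest.approx(2.7)
        assert stats.range == (0.0, 5.0)
        assert stats.sd == pytest.approx(np.std(distances, ddof=1))

    def test_rigid_transform_invariance(self, scene_noiseless, rng):
        verts = scene_noiseless.mesh.vertices
        centers = scene_noiseless.marker_centers
        normals = scene_noiseless.marker_normals
        delta = np.full(len(verts), 2.0)
        for c in centers:
            delta[np.linalg.norm(verts - c, axis=1) < 0.006] = 0.0
        diff = DifferentialMap(
            mesh=scene_noiseless.mesh, delta_t=delta,
            colors=np.zeros((len(verts), 3), dtype=np.uint8),
        )
        stats_a = marker_halo_error(diff, centers, normals)

        r = Rotation.from_rotvec(rng.normal(0, 0.7, 3)).as_matrix()
        t = rng.normal(0, 0.3, 3)
        moved = scene_noiseless.mesh.copy()
        moved.vertices = verts @ r.T + t
        moved.normals = scene_noiseless.mesh.normals @ r.T
        diff_b = DifferentialMap(
            mesh=moved, delta_t=delta, colors=np.zeros((len(verts), 3), dtype=np.uint8)
        )
        stats_b = marker_halo_error(diff_b, centers @ r.T + t, normals @ r.T)
        np.testing.assert_allclose(stats_a.per_marker, stats_b.per_marker, atol=1e-9)

    def test_marker_without_halo_reported_missing(self):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=0.05)
        verts = np.asarray(tm.vertices)
        delta = np.full(len(verts), 2.0)
        good = np.array([0.05, 0.0, 0.0])
        delta[np.linalg.norm(verts - good, axis=1) < 0.008] = 0.0
        diff = DifferentialMap(
            mesh=LimbMesh(verts, np.asarray(tm.faces)), delta_t=delta,
            colors=np.zeros((len(verts), 3), dtype=np.uint8),
        )
        centers = np.array([good, [-0.05, 0.0, 0.0]])
        stats = marker_halo_error(diff, centers)
        assert len(stats.per_marker) == 1
        assert stats.missing_markers == 1

    def test_perturbed_poses_shift_halo_into_expected_band(self, scene_noisy, ramp_model):
        """Monte-Carlo oracle: texturing both conditions with poses perturbed
        by ~2 mm produces a median misalignment of a few millimetres."""
        from thermomesh.colormap import encode_temperatures
        from thermomesh.texturing import assign_vertex_colors, colors_to_temperatures, compute_visibility

        scene = scene_noisy
        medians = []
        for trial in range(3):
            rng = np.random.default_rng(300 + trial)
            textured = {}
            for cond in ("rest", "post_walk"):
                images = [encode_temperatures(f.values) for f in scene.frames[cond]]
                poses = [
                    p.compose_delta(rng.normal(0, 8e-4, 3), rng.normal(0, 2e-3, 3))
                    for p in scene.poses
                ]
                asg = compute_visibility(scene.mesh, scene.camera, poses)
                textured[cond] = colors_to_temperatures(
                    assign_vertex_colors(scene.mesh, images, asg, blend=True), ramp_model
                )
            diff = differential_map(textured["post_walk"], textured["rest"])
            stats = marker_halo_error(diff, scene.marker_centers, scene.marker_normals)
            medians.append(stats.median)
        assert 0.3 <= np.median(medians) <= 4.0


class TestHotspots:
    def make_mesh_with_temps(self, temps):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=0.05)
        mesh = LimbMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        mesh.vertex_temperature = temps(np.asarray(tm.vertices))
        return mesh

    def test_constant_below_threshold_empty(self):
        mesh = self.make_mesh_with_temps(lambda v: np.full(len(v), 31.0))
        assert summarize_hotspots(mesh, threshold=34.0) == []

    def test_single_spot_single_component_contains_peak(self):
        center = np.array([0.05, 0.0, 0.0])

        def field(v):
            d2 = ((v - center) ** 2).sum(axis=1)
            return 31.0 + 5.0 * np.exp(-d2 / (2 * 0.01**2))

        mesh = self.make_mesh_with_temps(field)
        spots = summarize_hotspots(mesh, threshold=34.0)
        assert len(spots) == 1
        assert spots[0]["peak_c"] == pytest.approx(36.0, abs=0.05)
        assert spots[0]["area_m2"] > 0

    def test_two_disjoint_spots_two_components_flood_fill_oracle(self):
        c1 = np.array([0.05, 0.0, 0.0])
        c2 = np.array([-0.05, 0.0, 0.0])

        def field(v):
            d1 = ((v - c1) ** 2).sum(axis=1)
            d2 = ((v - c2) ** 2).sum(axis=1)
            return 31.0 + 5.0 * (np.exp(-d1 / 2e-4) + np.exp(-d2 / 2e-4))

        mesh = self.make_mesh_with_temps(field)
        spots = summarize_hotspots(mesh, threshold=34.0)
        assert len(spots) == 2

        # Flood-fill oracle on the vertex adjacency graph.
        import networkx as nx

        hot = np.flatnonzero(mesh.vertex_temperature > 34.0)
        g = nx.Graph()
        g.add_nodes_from(hot)
        hotset = set(hot.tolist())
        for f in mesh.faces:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                if f[i] in hotset and f[j] in hotset:
                    g.add_edge(f[i], f[j])
        assert nx.number_connected_components(g) == 2
        total = sum(s["n_vertices"] for s in spots)
        assert total == len(hot)
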