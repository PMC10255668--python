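"""Per-vertex texturing of the limb mesh from registered thermal images.

Once every view has a pose, each mesh vertex is coloured from the encoded
(false-colour) thermal images: a vertex is visible in a view when it
projects inside the image, faces the camera, and passes a depth-buffer
occlusion test; its weight in that view is the cosine of the viewing angle.
Colours are taken from the single best view, or blended across all visible
views with normalized cosine weights -- blending smooths seams between
views but creates colours that lie off the colormap arc, which is exactly
why the decoding stage uses a smooth inverse model rather than a lookup
table.  Vertices visible in no view get a reserved sentinel colour and a
NaN temperature.

The module also provides scan clean-up: keeping the largest connected
component, discarding interior geometry that no outside direction can see,
and decimating to a workable vertex count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .camera import CameraModel, ViewPose, project
from .colormap import InverseColorModel
from .mesh import LimbMesh, SENTINEL_RGB
from .raster import render_depth

#: Depth-buffer tolerance (m) for the occlusion test; covers interpolation
#: error of the z-buffer across pixel-sized triangles.
OCCLUSION_EPS = 5e-4

#: Depth tolerance (m) for accepting an individual pixel as showing the
#: same surface patch as the vertex being textured.  Pixels whose z-buffer
#: depth differs more (background, a fiducial cube in front of skin, an
#: occluding fold) are excluded from the bilinear colour sample.
SAMPLE_DEPTH_TOL = 2e-3

#: Largest number of images a single texturing pass accepts.
MAX_FRAMES = 10


@dataclass
class ViewAssignment:
    """Per-vertex visibility, weights and best view over a set of views."""

    visible: np.ndarray     # (n_views, n_vertices) bool
    weights: np.ndarray     # (n_views, n_vertices) float in [0, 1]; 0 iff invisible
    pixels: np.ndarray      # (n_views, n_vertices, 2) projected (u, v)
    best_view: np.ndarray   # (n_vertices,) int; -1 where never visible
    neighbor_ok: np.ndarray # (n_views, n_vertices, 4) depth-consistent bilinear pixels

    @property
    def n_views(self) -> int:
        return self.visible.shape[0]


def _bilinear_neighbors(uv: np.ndarray, width: int, height: int):
    u0 = np.clip(np.floor(uv[:, 0]).astype(int), 0, width - 1)
    v0 = np.clip(np.floor(uv[:, 1]).astype(int), 0, height - 1)
    u1 = np.minimum(u0 + 1, width - 1)
    v1 = np.minimum(v0 + 1, height - 1)
    return (u0, v0), (u1, v0), (u0, v1), (u1, v1)


def compute_visibility(
    mesh: LimbMesh,
    camera: CameraModel,
    poses: list[ViewPose],
    occlusion_eps: float = OCCLUSION_EPS,
    sample_depth_tol: float = SAMPLE_DEPTH_TOL,
    min_cos: float = 0.15,
) -> ViewAssignment:
    """Visibility and cosine weights of every vertex in every view.

    A vertex is visible in a view iff its projection falls inside the
    image, its normal faces the camera, the z-buffer rendered from the same
    pose shows no nearer surface at its pixel (tolerance ``occlusion_eps``),
    and at least one of the four bilinear neighbour pixels shows a surface
    at the vertex's own depth (tolerance ``sample_depth_tol``) -- the last
    condition keeps background, fiducial-cube and occluding-fold pixels out
    of the colour sample near silhouettes and depth discontinuities.
    ``min_cos`` additionally drops extreme grazing views of a vertex, whose
    pixel footprint spans several millimetres of surface and samples the
    temperature field far from the vertex.
    """
    if len(poses) == 0:
        raise ValueError("compute_visibility requires at least one view")
    n = mesh.n_vertices
    width, height = camera.image_size
    visible = np.zeros((len(poses), n), dtype=bool)
    weights = np.zeros((len(poses), n))
    pixels = np.zeros((len(poses), n, 2))
    neighbor_ok = np.zeros((len(poses), n, 4), dtype=bool)

    for k, pose in enumerate(poses):
        uv = project(camera, pose, mesh.vertices, strict=False)
        pixels[k] = np.nan_to_num(uv, nan=-1e9)
        cam_z = pose.transform(mesh.vertices)[:, 2]
        inside = (
            (cam_z > 0)
            & (uv[:, 0] >= 0) & (uv[:, 0] <= width - 1)
            & (uv[:, 1] >= 0) & (uv[:, 1] <= height - 1)
        )
        view_dir = pose.camera_center[None, :] - mesh.vertices
        view_dir = view_dir / np.maximum(np.linalg.norm(view_dir, axis=1, keepdims=True), 1e-12)
        cosang = (mesh.normals * view_dir).sum(axis=1)
        facing = cosang > max(min_cos, 0.0)

        depth, _ = render_depth(camera, pose, mesh.vertices, mesh.faces)
        cand = np.flatnonzero(inside & facing)
        px = np.clip(np.rint(pixels[k, cand]).astype(int), [0, 0], [width - 1, height - 1])
        zbuf = depth[px[:, 1], px[:, 0]]
        unoccluded = cam_z[cand] <= zbuf + occlusion_eps
        cand = cand[unoccluded]

        for j, (uu, vv) in enumerate(_bilinear_neighbors(pixels[k, cand], width, height)):
            neighbor_ok[k, cand, j] = np.abs(depth[vv, uu] - cam_z[cand]) <= sample_depth_tol
        vis = np.zeros(n, dtype=bool)
        vis[cand] = neighbor_ok[k, cand].any(axis=1)
        visible[k] = vis
        weights[k, vis] = np.clip(cosang[vis], 0.0, 1.0)
        neighbor_ok[k, ~vis] = False

    best = np.where(visible.any(axis=0), np.argmax(weights, axis=0), -1)
    return ViewAssignment(
        visible=visible, weights=weights, pixels=pixels, best_view=best,
        neighbor_ok=neighbor_ok,
    )


def bilinear_sample(
    image: np.ndarray, uv: np.ndarray, neighbor_ok: np.ndarray | None = None
) -> np.ndarray:
    """Bilinear sample of an (H, W, C) image at pixel coordinates (n, 2).

    ``neighbor_ok`` (n, 4) optionally masks the four neighbour pixels (order
    top-left, top-right, bottom-left, bottom-right); masked-out neighbours
    are dropped and the remaining bilinear weights renormalized, so colours
    never mix across depth discontinuities.
    """
    h, w = image.shape[:2]
    u = np.clip(uv[:, 0], 0.0, w - 1.0)
    v = np.clip(uv[:, 1], 0.0, h - 1.0)
    u0 = np.floor(u).astype(int)
    v0 = np.floor(v).astype(int)
    u1 = np.minimum(u0 + 1, w - 1)
    v1 = np.minimum(v0 + 1, h - 1)
    fu = u - u0
    fv = v - v0
    wts = np.stack(
        [(1 - fu) * (1 - fv), fu * (1 - fv), (1 - fu) * fv, fu * fv], axis=1
    )
    if neighbor_ok is not None:
        wts = wts * neighbor_ok
        total = wts.sum(axis=1, keepdims=True)
        fallback = total[:, 0] <= 0
        if fallback.any():  # no consistent neighbour: plain bilinear
            wts[fallback] = np.stack(
                [(1 - fu) * (1 - fv), fu * (1 - fv), (1 - fu) * fv, fu * fv], axis=1
            )[fallback]
            total = wts.sum(axis=1, keepdims=True)
        wts = wts / total
    img = image.astype(np.float64)
    corners = np.stack([img[v0, u0], img[v0, u1], img[v1, u0], img[v1, u1]], axis=1)
    return (wts[:, :, None] * corners).sum(axis=1)


def assign_vertex_colors(
    mesh: LimbMesh,
    images: list[np.ndarray],
    assignment: ViewAssignment,
    blend: bool = True,
) -> LimbMesh:
    """Colour every visible vertex from the encoded thermal images.

    With ``blend`` the colour is the cosine-weighted average over all views
    that see the vertex (this reproduces the seam smoothing that generates
    off-colormap colours); without it, a bilinear sample from the single
    best view.  Invisible-everywhere vertices get the sentinel colour.

    Returns a copy of ``mesh`` with ``vertex_rgb`` set.
    """
    if len(images) > MAX_FRAMES:
        raise ValueError(f"texturing accepts at most {MAX_FRAMES} images, got {len(images)}")
    if len(images) != assignment.n_views:
        raise ValueError("one image per view is required")
    n = mesh.n_vertices
    out = mesh.copy()
    colors = np.zeros((n, 3))

    if blend:
        wsum = np.zeros(n)
        for k, img in enumerate(images):
            vis = assignment.visible[k]
            if not vis.any():
                continue
            sample = bilinear_sample(
                img, assignment.pixels[k, vis], assignment.neighbor_ok[k, vis]
            )
            w = assignment.weights[k, vis][:, None]
            colors[vis] += w * sample
            wsum[vis] += assignment.weights[k, vis]
        ok = wsum > 0
        colors[ok] /= wsum[ok, None]
    else:
        ok = assignment.best_view >= 0
        for k, img in enumerate(images):
            sel = ok & (assignment.best_view == k)
            if not sel.any():
                continue
            colors[sel] = bilinear_sample(
                img, assignment.pixels[k, sel], assignment.neighbor_ok[k, sel]
            )

    rgb = np.rint(colors).astype(np.uint8)
    # Keep the sentinel reserved for truly untextured vertices.
    is_sentinel = np.all(rgb == SENTINEL_RGB, axis=1)
    rgb[ok & is_sentinel] = (1, 1, 1)
    rgb[~ok] = SENTINEL_RGB
    out.vertex_rgb = rgb
    return out


def colors_to_temperatures(mesh: LimbMesh, model: InverseColorModel) -> LimbMesh:
    """Decode per-vertex RGB into per-vertex temperature (degC).

    Sentinel (untextured) vertices get NaN; every other vertex gets the
    inverse-model prediction, finite and inside the colormap anchors even
    for blended seam colours.
    """
    if mesh.vertex_rgb is None:
        raise ValueError("mesh has no vertex colours to decode")
    out = mesh.copy()
    rgb = mesh.vertex_rgb
    temp = model.predict(rgb.astype(np.float64))
    sentinel = np.all(rgb == np.asarray(SENTINEL_RGB, dtype=np.uint8), axis=1)
    temp = np.where(sentinel, np.nan, temp)
    out.vertex_temperature = temp
    return out


# ---------------------------------------------------------------------------
# Scan clean-up and decimation
# ---------------------------------------------------------------------------

def decimate_vertex_clustering(
    vertices: np.ndarray,
    faces: np.ndarray,
    target_vertices: int,
    tolerance: float = 0.10,
    max_iter: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid vertex-clustering decimation to ``target_vertices`` (+/- tolerance).

    Vertices are binned on a uniform grid, each occupied cell collapses to
    the mean of its vertices, and degenerate / duplicate faces are dropped.
    The cell size is found by bisection so the output vertex count lands
    within the tolerance band.  Geometric error is bounded by the cell
    diagonal, which is of the order of the output mesh's edge length.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if len(vertices) <= target_vertices:
        return vertices.copy(), faces.copy()

    extent = vertices.max(axis=0) - vertices.min(axis=0)
    vol = np.prod(extent[extent > 0])
    h_lo = (vol / max(len(vertices), 1)) ** (1.0 / 3.0) / 4.0   # too fine
    h_hi = float(np.max(extent))                                # too coarse

    def cluster(h):
        keys = np.floor((vertices - vertices.min(axis=0)) / h).astype(np.int64)
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        reps = np.zeros((len(uniq), 3))
        counts = np.bincount(inverse).astype(np.float64)
        for d in range(3):
            reps[:, d] = np.bincount(inverse, weights=vertices[:, d]) / counts
        f = inverse[faces]
        good = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 2] != f[:, 0])
        f = f[good]
        # Drop duplicated faces regardless of orientation/rotation.
        f_sorted = np.sort(f, axis=1)
        _, first = np.unique(f_sorted, axis=0, return_index=True)
        f = f[np.sort(first)]
        used = np.unique(f)
        remap = -np.ones(len(reps), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return reps[used], remap[f]

    lo, hi = h_lo, h_hi
    best = None
    for _ in range(max_iter):
        h = np.sqrt(lo * hi)
        v2, f2 = cluster(h)
        n = len(v2)
        if best is None or abs(n - target_vertices) < abs(len(best[0]) - target_vertices):
            best = (v2, f2)
        if abs(n - target_vertices) <= tolerance * target_vertices / 2.0:
            return v2, f2
        if n > target_vertices:
            lo = h
        else:
            hi = h
    return best


def _exterior_visible_mask(
    vertices: np.ndarray, faces: np.ndarray, n_directions: int = 14
) -> np.ndarray:
    """Vertices visible from at least one surrounding viewpoint."""
    from .camera import look_at_pose

    center = vertices.mean(axis=0)
    radius = np.linalg.norm(vertices - center, axis=1).max()
    cam = CameraModel(
        focal=(200.0, 200.0), principal_point=(159.5, 119.5), image_size=(320, 240)
    )
    dirs = trimesh.creation.icosphere(subdivisions=1).vertices[:n_directions]
    seen = np.zeros(len(vertices), dtype=bool)
    probe = LimbMesh(vertices, faces)
    for d in np.asarray(dirs, dtype=np.float64):
        eye = center + d / np.linalg.norm(d) * radius * 3.0
        pose = look_at_pose(eye, center)
        assignment = compute_visibility(probe, cam, [pose])
        seen |= assignment.visible[0]
    return seen


def clean_mesh(
    raw: LimbMesh,
    target_vertices: int = 16000,
    remove_interior: bool = True,
) -> LimbMesh:
    """Clean a raw surface scan down to a workable limb mesh.

    Keeps the largest connected component, drops degenerate and duplicate
    faces, removes interior vertices that no outside viewpoint can see, and
    decimates to ``target_vertices`` (+/-10%) by vertex clustering.
    """
    tm = trimesh.Trimesh(raw.vertices.copy(), raw.faces.copy(), process=False)
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    tm.remove_unreferenced_vertices()

    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: len(p.vertices))
    if len(tm.vertices) == 0:
        raise ValueError("mesh is empty after clean-up")

    if remove_interior and len(tm.vertices) > 0:
        verts = np.asarray(tm.vertices)
        faces = np.asarray(tm.faces)
        seen = _exterior_visible_mask(verts, faces)
        # Keep faces whose vertices are all exterior-visible; tolerate the
        # odd grazing vertex by a second pass keeping any face with >= 2.
        keep_face = seen[faces].sum(axis=1) >= 2
        if keep_face.any() and not keep_face.all():
            tm = trimesh.Trimesh(verts, faces[keep_face], process=False)
            tm.remove_unreferenced_vertices()
            parts = tm.split(only_watertight=False)
            if len(parts) > 1:
                tm = max(parts, key=lambda p: len(p.vertices))

    v, f = np.asarray(tm.vertices), np.asarray(tm.faces)
    if len(v) > target_vertices * 1.1:
        v, f = decimate_vertex_clustering(v, f, target_vertices)
    if len(v) == 0:
        raise ValueError("mesh is empty after decimation")
    return LimbMesh(v, f)
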