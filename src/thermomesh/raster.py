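"""Software z-buffer rasterizer for mesh attributes.

Renders a triangle mesh through the distorted pinhole camera into a small
(320 x 240) raster, interpolating one scalar attribute per vertex with
perspective-correct barycentric weights.  Used to synthesize thermal frames
(attribute = temperature), to build shading images for mutual-information
pose refinement, and to answer per-vertex visibility queries via the depth
and face-id buffers.

The inner loop is JIT-compiled with numba; triangles whose vertices are all
in front of the camera are scan-converted over their pixel bounding box with
an edge-function inside test.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .camera import CameraModel, ViewPose, project


class EmptyRenderError(RuntimeError):
    """No triangle of the mesh rasterized inside the image."""


@njit(cache=True)
def _rasterize_kernel(uv, z, faces, attr, height, width):  # pragma: no cover - numba
    depth = np.full((height, width), np.inf)
    image = np.full((height, width), np.nan)
    face_id = np.full((height, width), -1, dtype=np.int64)
    for f in range(faces.shape[0]):
        i0, i1, i2 = faces[f, 0], faces[f, 1], faces[f, 2]
        z0, z1, z2 = z[i0], z[i1], z[i2]
        if z0 <= 1e-9 or z1 <= 1e-9 or z2 <= 1e-9:
            continue
        x0, y0 = uv[i0, 0], uv[i0, 1]
        x1, y1 = uv[i1, 0], uv[i1, 1]
        x2, y2 = uv[i2, 0], uv[i2, 1]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0.0:
            continue
        xmin = int(np.floor(min(x0, min(x1, x2))))
        xmax = int(np.ceil(max(x0, max(x1, x2))))
        ymin = int(np.floor(min(y0, min(y1, y2))))
        ymax = int(np.ceil(max(y0, max(y1, y2))))
        if xmax < 0 or ymax < 0 or xmin > width - 1 or ymin > height - 1:
            continue
        xmin = max(xmin, 0)
        ymin = max(ymin, 0)
        xmax = min(xmax, width - 1)
        ymax = min(ymax, height - 1)
        inv_area = 1.0 / area
        iz0, iz1, iz2 = 1.0 / z0, 1.0 / z1, 1.0 / z2
        a0, a1, a2 = attr[i0] * iz0, attr[i1] * iz1, attr[i2] * iz2
        for py in range(ymin, ymax + 1):
            for px in range(xmin, xmax + 1):
                w0 = ((x1 - px) * (y2 - py) - (x2 - px) * (y1 - py)) * inv_area
                w1 = ((x2 - px) * (y0 - py) - (x0 - px) * (y2 - py)) * inv_area
                w2 = 1.0 - w0 - w1
                if w0 < 0.0 or w1 < 0.0 or w2 < 0.0:
                    continue
                zinv = w0 * iz0 + w1 * iz1 + w2 * iz2
                zp = 1.0 / zinv
                if zp < depth[py, px]:
                    depth[py, px] = zp
                    image[py, px] = (w0 * a0 + w1 * a1 + w2 * a2) * zp
                    face_id[py, px] = f
    return image, depth, face_id


def render_attribute(
    camera: CameraModel,
    pose: ViewPose,
    vertices: np.ndarray,
    faces: np.ndarray,
    vertex_attr: np.ndarray,
    background: float = np.nan,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one scalar per-vertex attribute through ``camera`` at ``pose``.

    Returns
    -------
    image : (H, W) float array
        Perspective-correct interpolated attribute; ``background`` where no
        triangle covers the pixel.
    depth : (H, W) float array
        Camera-frame z of the nearest surface, ``inf`` on background.
    face_id : (H, W) int array
        Index of the visible face per pixel, -1 on background.

    Raises
    ------
    EmptyRenderError
        If the mesh lies entirely outside the view frustum.
    """
    width, height = camera.image_size
    cam_pts = pose.transform(np.asarray(vertices, dtype=np.float64))
    uv = project(camera, pose, vertices, strict=False)
    uv = np.ascontiguousarray(np.nan_to_num(uv, nan=-1e9), dtype=np.float64)
    image, depth, face_id = _rasterize_kernel(
        uv,
        np.ascontiguousarray(cam_pts[:, 2]),
        np.ascontiguousarray(faces, dtype=np.int64),
        np.ascontiguousarray(vertex_attr, dtype=np.float64),
        height,
        width,
    )
    if not np.any(face_id >= 0):
        raise EmptyRenderError("mesh renders to an empty image (outside the frustum?)")
    if not np.isnan(background):
        image = np.where(face_id >= 0, image, background)
    return image, depth, face_id


def render_depth(
    camera: CameraModel, pose: ViewPose, vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Depth and face-id buffers only (attribute discarded)."""
    _, depth, face_id = render_attribute(
        camera, pose, vertices, faces, np.zeros(len(vertices)), background=np.nan
    )
    return depth, face_id


def lambert_shading(
    vertices: np.ndarray, normals: np.ndarray, camera_center: np.ndarray
) -> np.ndarray:
    """Per-vertex Lambertian shading term max(0, n . v) toward the camera."""
    v = camera_center[None, :] - vertices
    v = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    return np.clip((normals * v).sum(axis=1), 0.0, 1.0)
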