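"""Pinhole camera model with radial lens distortion, and planar-target calibration.

The thermal camera is modelled as a standard pinhole with focal lengths
(fx, fy), principal point (cx, cy), zero skew and a two-term radial
distortion polynomial ``1 + k1 r^2 + k2 r^4`` applied to normalized image
coordinates (tangential terms are carried but default to zero).  World
lengths are metres, image coordinates pixels, with pixel centres at integer
coordinates and (0, 0) the top-left pixel.

Calibration follows the classic planar-target procedure: per-view
homographies give a closed-form initialization of the intrinsics, after
which everything -- intrinsics, distortion and per-view poses -- is refined
jointly by Levenberg-Marquardt on the reprojection error.  A calibration is
accepted when the mean reprojection error is below one pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

#: Thermal sensor raster size, (width, height) pixels.
DEFAULT_IMAGE_SIZE = (320, 240)

#: Mean-reprojection-error threshold (pixels) below which a calibration
#: is accepted.
CALIBRATION_ACCEPT_PX = 1.0


class BehindCameraError(ValueError):
    """A point to be projected has non-positive depth in the camera frame."""


class DegenerateViewsError(ValueError):
    """The calibration views do not constrain the intrinsics."""


@dataclass
class CameraModel:
    """Pinhole intrinsics plus two-term radial / two-term tangential distortion."""

    focal: tuple[float, float] = (736.5414, 742.3704)
    principal_point: tuple[float, float] = (274.4383, 145.2130)
    skew: float = 0.0
    radial: tuple[float, float] = (0.0, 0.0)
    tangential: tuple[float, float] = (0.0, 0.0)
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE  # (width, height)

    def __post_init__(self) -> None:
        if self.focal[0] <= 0 or self.focal[1] <= 0:
            raise ValueError(f"focal lengths must be positive, got {self.focal}")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 intrinsic matrix K."""
        fx, fy = self.focal
        cx, cy = self.principal_point
        return np.array([[fx, self.skew, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    def distort(self, xy: np.ndarray) -> np.ndarray:
        """Apply lens distortion to normalized coordinates, shape (..., 2)."""
        xy = np.asarray(xy, dtype=np.float64)
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        k1, k2 = self.radial
        p1, p2 = self.tangential
        radial = 1.0 + k1 * r2 + k2 * r2 * r2
        xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def undistort(self, xy_d: np.ndarray, iters: int = 20) -> np.ndarray:
        """Invert :meth:`distort` by fixed-point iteration on normalized coords."""
        xy_d = np.asarray(xy_d, dtype=np.float64)
        xy = xy_d.copy()
        for _ in range(iters):
            delta = self.distort(xy) - xy
            xy = xy_d - delta
        return xy

    def normalized_to_pixel(self, xy: np.ndarray) -> np.ndarray:
        fx, fy = self.focal
        cx, cy = self.principal_point
        u = fx * xy[..., 0] + self.skew * xy[..., 1] + cx
        v = fy * xy[..., 1] + cy
        return np.stack([u, v], axis=-1)

    def pixel_to_normalized(self, uv: np.ndarray) -> np.ndarray:
        fx, fy = self.focal
        cx, cy = self.principal_point
        uv = np.asarray(uv, dtype=np.float64)
        y = (uv[..., 1] - cy) / fy
        x = (uv[..., 0] - cx - self.skew * y) / fx
        return np.stack([x, y], axis=-1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "focal_length": list(self.focal),
            "principal_point": list(self.principal_point),
            "skew": self.skew,
            "radial_distortion": list(self.radial),
            "tangential_distortion": list(self.tangential),
            "image_size": list(self.image_size),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            focal=tuple(raw["focal_length"]),
            principal_point=tuple(raw["principal_point"]),
            skew=raw.get("skew", 0.0),
            radial=tuple(raw.get("radial_distortion", (0.0, 0.0))),
            tangential=tuple(raw.get("tangential_distortion", (0.0, 0.0))),
            image_size=tuple(raw.get("image_size", DEFAULT_IMAGE_SIZE)),
        )


@dataclass
class ViewPose:
    """Rigid world-to-camera transform: ``x_cam = R @ x_world + t``."""

    rotation: np.ndarray   # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,), metres

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal to 1e-9")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation matrix has negative determinant")

    def transform(self, points: np.ndarray) -> np.ndarray:
        """World points (..., 3) -> camera-frame points."""
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def inverse(self) -> "ViewPose":
        return ViewPose(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def camera_center(self) -> np.ndarray:
        """Camera origin expressed in world coordinates."""
        return -self.rotation.T @ self.translation

    def compose_delta(self, rvec: np.ndarray, tvec: np.ndarray) -> "ViewPose":
        """Left-multiply a small axis-angle/translation increment."""
        dr = Rotation.from_rotvec(np.asarray(rvec, dtype=np.float64)).as_matrix()
        return ViewPose(dr @ self.rotation, dr @ self.translation + np.asarray(tvec))

    def to_dict(self) -> dict:
        q = Rotation.from_matrix(self.rotation).as_quat()  # (x, y, z, w)
        return {
            "quaternion_xyzw": [float(v) for v in q],
            "translation_m": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ViewPose":
        r = Rotation.from_quat(raw["quaternion_xyzw"]).as_matrix()
        return cls(r, np.asarray(raw["translation_m"], dtype=np.float64))


def look_at_pose(eye: np.ndarray, target: np.ndarray, up: np.ndarray = (0.0, 0.0, 1.0)) -> ViewPose:
    """Camera at ``eye`` looking toward ``target``; image +y points away from ``up``.

    Camera axes follow the computer-vision convention: +x right, +y down,
    +z forward (into the scene).
    """
    eye = np.asarray(eye, dtype=np.float64)
    fwd = np.asarray(target, dtype=np.float64) - eye
    fwd = fwd / np.linalg.norm(fwd)
    up = np.asarray(up, dtype=np.float64)
    right = np.cross(fwd, up)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        right = np.cross(fwd, (1.0, 0.0, 0.0))
        nr = np.linalg.norm(right)
    right = right / nr
    down = np.cross(fwd, right)
    r = np.stack([right, down, fwd])
    return ViewPose(r, -r @ eye)


def project(
    camera: CameraModel, pose: ViewPose, points: np.ndarray, *, strict: bool = True
) -> np.ndarray:
    """Project world points (..., 3) to pixel coordinates (..., 2).

    Points are transformed to the camera frame, perspective-divided,
    distorted and mapped through the intrinsics.

    Raises
    ------
    BehindCameraError
        If ``strict`` and any point has non-positive depth.
    """
    pts = np.asarray(points, dtype=np.float64)
    cam = pose.transform(pts)
    z = cam[..., 2]
    if strict and np.any(z <= 0):
        raise BehindCameraError(
            f"{int(np.sum(z <= 0))} point(s) at non-positive depth (min z = {z.min():.4g} m)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = cam[..., :2] / z[..., None]
    return camera.normalized_to_pixel(camera.distort(xy))


# ---------------------------------------------------------------------------
# Planar calibration target
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChessboardSpec:
    """Planar calibration grid: square size and board extent, metres.

    The default mirrors a 300 x 180 mm board of 30 mm squares; inner corners
    form a (squares_x - 1) x (squares_y - 1) grid whose first corner sits one
    square in from the board origin.
    """

    square_size: float = 0.030
    board_size: tuple[float, float] = (0.300, 0.180)

    @property
    def squares(self) -> tuple[int, int]:
        return (
            int(round(self.board_size[0] / self.square_size)),
            int(round(self.board_size[1] / self.square_size)),
        )

    @property
    def inner_corners(self) -> tuple[int, int]:
        nx, ny = self.squares
        return nx - 1, ny - 1


def corner_grid(spec: ChessboardSpec = ChessboardSpec()) -> np.ndarray:
    """Inner-corner world coordinates of a planar chessboard, z = 0, row-major.

    Returns shape (n_corners, 3) in metres; the first corner is at
    ``(square_size, square_size, 0)`` measured from the board corner.
    """
    if spec.square_size <= 0:
        raise ValueError("square size must be positive")
    nx, ny = spec.inner_corners
    if nx < 1 or ny < 1:
        raise ValueError(
            f"board {spec.board_size} with {spec.square_size} m squares has no inner corners"
        )
    xs = (np.arange(1, nx + 1)) * spec.square_size
    ys = (np.arange(1, ny + 1)) * spec.square_size
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    return pts


@dataclass
class CalibrationResult:
    camera: CameraModel
    per_view_poses: list[ViewPose]
    mean_reprojection_error: float  # pixels
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        self.accepted = self.mean_reprojection_error < CALIBRATION_ACCEPT_PX


def _homography_dlt(obj_xy: np.ndarray, img_uv: np.ndarray) -> np.ndarray:
    """Planar homography by normalized DLT; obj_xy, img_uv of shape (n, 2)."""

    def normalize(p):
        mean = p.mean(axis=0)
        scale = np.sqrt(2.0) / np.mean(np.linalg.norm(p - mean, axis=1))
        tform = np.array([[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1]])
        ph = np.column_stack([p, np.ones(len(p))]) @ tform.T
        return ph, tform

    src, t_src = normalize(obj_xy)
    dst, t_dst = normalize(img_uv)
    n = len(src)
    a = np.zeros((2 * n, 9))
    a[0::2, 0:3] = src
    a[0::2, 6:9] = -dst[:, 0:1] * src
    a[1::2, 3:6] = src
    a[1::2, 6:9] = -dst[:, 1:2] * src
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-12 * s[0]:
        raise DegenerateViewsError("degenerate correspondences: homography is rank deficient")
    h = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h @ t_src
    return h / h[2, 2]


def _intrinsics_from_homographies(hs: list[np.ndarray]) -> np.ndarray:
    """Closed-form K from >=3 homographies via the absolute-conic constraints."""

    def v_ij(h, i, j):
        return np.array(
            [
                h[0, i] * h[0, j],
                h[0, i] * h[1, j] + h[1, i] * h[0, j],
                h[1, i] * h[1, j],
                h[2, i] * h[0, j] + h[0, i] * h[2, j],
                h[2, i] * h[1, j] + h[1, i] * h[2, j],
                h[2, i] * h[2, j],
            ]
        )

    rows = []
    for h in hs:
        rows.append(v_ij(h, 0, 1))
        rows.append(v_ij(h, 0, 0) - v_ij(h, 1, 1))
    a = np.asarray(rows)
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-10 * s[0]:
        raise DegenerateViewsError("calibration views are degenerate (identical orientations?)")
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12**2
    if abs(denom) < 1e-16 or b11 == 0:
        raise DegenerateViewsError("absolute-conic estimate is singular")
    cy = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13**2 + cy * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0:
        raise DegenerateViewsError("absolute-conic estimate is not positive definite")
    fx = np.sqrt(lam / b11)
    fy = np.sqrt(lam * b11 / denom)
    skew = -b12 * fx**2 * fy / lam
    cx = skew * cy / fy - b13 * fx**2 / lam
    return np.array([[fx, skew, cx], [0, fy, cy], [0, 0, 1]])


def _extrinsics_from_homography(k: np.ndarray, h: np.ndarray) -> ViewPose:
    kinv = np.linalg.inv(k)
    h1, h2, h3 = (kinv @ h[:, i] for i in range(3))
    lam = 1.0 / np.linalg.norm(h1)
    r1, r2 = lam * h1, lam * h2
    r3 = np.cross(r1, r2)
    r = np.stack([r1, r2, r3], axis=1)
    # Nearest rotation matrix.
    u, _, vt = np.linalg.svd(r)
    r = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    t = lam * h3
    if t[2] < 0:  # board must be in front of the camera
        r = np.stack([-r1, -r2, np.cross(-r1, -r2)], axis=1)
        u, _, vt = np.linalg.svd(r)
        r = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
        t = -t
    return ViewPose(r, t)


def calibrate(
    views: list[tuple[np.ndarray, np.ndarray]],
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    fit_tangential: bool = False,
    max_iter: int = 200,
) -> CalibrationResult:
    """Calibrate intrinsics and distortion from planar-grid correspondences.

    Parameters
    ----------
    views
        One ``(object_points, image_points)`` pair per view: object points
        (n, 3) on the z=0 board plane in metres, image points (n, 2) pixels.
        At least 3 views are required.
    fit_tangential
        Also refine the two tangential coefficients (default: keep at 0).

    Returns
    -------
    CalibrationResult
        Refined camera, per-view poses, mean reprojection error (pixels) and
        the accepted flag (mean error < 1 px).
    """
    if len(views) < 3:
        raise DegenerateViewsError(
            f"planar calibration needs >= 3 views, got {len(views)}"
        )
    obj = [np.asarray(o, dtype=np.float64) for o, _ in views]
    img = [np.asarray(i, dtype=np.float64) for _, i in views]
    for o in obj:
        if not np.allclose(o[:, 2], 0.0):
            raise ValueError("object points must lie on the z=0 plane")

    hs = [_homography_dlt(o[:, :2], i) for o, i in zip(obj, img)]
    k0 = _intrinsics_from_homographies(hs)
    poses0 = [_extrinsics_from_homography(k0, h) for h in hs]

    n_views = len(views)
    x0 = np.concatenate(
        [
            [k0[0, 0], k0[1, 1], k0[0, 2], k0[1, 2], 0.0, 0.0],  # fx fy cx cy k1 k2
            [0.0, 0.0] if fit_tangential else [],
            np.concatenate(
                [
                    np.concatenate(
                        [Rotation.from_matrix(p.rotation).as_rotvec(), p.translation]
                    )
                    for p in poses0
                ]
            ),
        ]
    )
    n_intr = 8 if fit_tangential else 6

    def unpack(x):
        fx, fy, cx, cy, k1, k2 = x[:6]
        p1, p2 = (x[6], x[7]) if fit_tangential else (0.0, 0.0)
        cam = CameraModel(
            focal=(fx, fy), principal_point=(cx, cy), radial=(k1, k2),
            tangential=(p1, p2), image_size=image_size,
        )
        poses = []
        for i in range(n_views):
            seg = x[n_intr + 6 * i : n_intr + 6 * i + 6]
            poses.append(ViewPose(Rotation.from_rotvec(seg[:3]).as_matrix(), seg[3:]))
        return cam, poses

    def residuals(x):
        cam, poses = unpack(x)
        res = []
        for o, i, p in zip(obj, img, poses):
            res.append((project(cam, p, o, strict=False) - i).ravel())
        return np.concatenate(res)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=max_iter * len(x0))
    cam, poses = unpack(sol.x)
    errs = [
        np.linalg.norm(project(cam, p, o, strict=False) - i, axis=1)
        for o, i, p in zip(obj, img, poses)
    ]
    mean_err = float(np.mean(np.concatenate(errs)))
    return CalibrationResult(cam, poses, mean_err)
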