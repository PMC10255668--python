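"""Image-to-geometry registration of thermal frames against the limb mesh.

Each 2D thermal frame must be given a 6-DoF camera pose relative to the 3D
mesh.  Registration runs in two stages, mirroring the usual
coarse-alignment-then-refinement recipe:

1. *Fiducial initialization.*  The cold cube markers form compact blobs in
   the thermal image near the marker temperature; their centroids, matched
   to the known 3D marker centres, give a perspective-n-point problem solved
   by Levenberg-Marquardt from a platform-geometry (or multi-start) initial
   guess.  This automates the manual coarse alignment of interactive
   workflows.

2. *Mutual-information refinement.*  The pose is polished by maximizing the
   mutual information between the thermal frame and a rendered, pose-
   dependent surface attribute (Lambertian shading toward the camera), with
   derivative-free Nelder-Mead over small pose increments.  The returned
   pose never scores below the initial one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares, linear_sum_assignment, minimize
from scipy.spatial.transform import Rotation

from .camera import CameraModel, ViewPose, project
from .mesh import LimbMesh
from .raster import lambert_shading, render_attribute
from .synthetic import MARKER_TEMPERATURE
from .thermal_io import ThermalFrame


class DegenerateMarkersError(ValueError):
    """Fewer than three non-collinear marker correspondences."""


class EmptySilhouetteError(RuntimeError):
    """The initial pose renders the mesh entirely outside the image."""


@dataclass
class MarkerObservation:
    """One matched fiducial: image blob centroid and 3D marker centre."""

    marker_id: int
    image_point: np.ndarray  # (2,) pixels
    mesh_point: np.ndarray   # (3,) metres


@dataclass
class RegistrationResult:
    pose: ViewPose
    mi_score: float          # bits, at the final pose
    fiducial_rmse: float     # pixels, NaN if no fiducials were used
    converged: bool
    mi_initial: float = np.nan
    n_markers: int = 0


# ---------------------------------------------------------------------------
# Fiducial blob detection and matching
# ---------------------------------------------------------------------------

def detect_marker_blobs(
    frame: ThermalFrame,
    marker_temperature: float = MARKER_TEMPERATURE,
    tolerance: float = 1.0,
    min_pixels: int = 3,
) -> np.ndarray:
    """Centroids (u, v) of connected pixel blobs near the marker temperature.

    Pixels within ``tolerance`` degC of ``marker_temperature`` are grouped by
    8-connectivity; components smaller than ``min_pixels`` are discarded.
    Returns an (n, 2) array (possibly empty).
    """
    mask = np.abs(frame.values - marker_temperature) <= tolerance
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.empty((0, 2))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_pixels) + 1
    if len(keep) == 0:
        return np.empty((0, 2))
    # centroid returns (row, col) = (v, u)
    cents = np.asarray(ndimage.center_of_mass(mask, labels, index=keep))
    return cents[:, ::-1].copy()


def match_blobs_to_markers(
    blobs: np.ndarray,
    marker_centers: np.ndarray,
    marker_normals: np.ndarray | None,
    camera: CameraModel,
    nominal_pose: ViewPose,
    gate_px: float = 30.0,
) -> list[MarkerObservation]:
    """Assign detected blobs to 3D markers by predicted projection.

    Markers are projected under ``nominal_pose`` (known from the platform
    geometry); blobs and predictions are matched one-to-one by minimum total
    pixel distance, and pairs farther apart than ``gate_px`` are dropped.
    Markers facing away from the camera are excluded up front.
    """
    if len(blobs) == 0:
        return []
    centers = np.asarray(marker_centers, dtype=np.float64)
    idx = np.arange(len(centers))
    if marker_normals is not None:
        view_dir = nominal_pose.camera_center[None, :] - centers
        view_dir = view_dir / np.linalg.norm(view_dir, axis=1, keepdims=True)
        # Cubes protrude ~8 mm, so they remain visible slightly past the
        # silhouette (normal-to-view angles up to ~115 degrees).
        facing = (np.asarray(marker_normals) * view_dir).sum(axis=1) > -0.45
        centers, idx = centers[facing], idx[facing]
    if len(centers) == 0:
        return []
    pred = project(camera, nominal_pose, centers, strict=False)
    cost = np.linalg.norm(pred[:, None, :] - blobs[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    obs = []
    for r, c in zip(rows, cols):
        if cost[r, c] <= gate_px:
            obs.append(MarkerObservation(int(idx[r]), blobs[c], centers[r]))
    return obs


# ---------------------------------------------------------------------------
# Perspective-n-point pose estimation
# ---------------------------------------------------------------------------

def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(points) < 3 or s[1] < 1e-9 * max(s[0], 1e-12):
        raise DegenerateMarkersError(
            "pose estimation needs >= 3 non-collinear marker points"
        )


def _pnp_refine(
    obs_3d: np.ndarray,
    obs_2d: np.ndarray,
    camera: CameraModel,
    pose0: ViewPose,
    center_prior: tuple[np.ndarray, float] | None = None,
) -> tuple[ViewPose, float]:
    r0 = Rotation.from_matrix(pose0.rotation).as_rotvec()
    x0 = np.concatenate([r0, pose0.translation])

    def reproj(x):
        pose = ViewPose(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])
        uv = project(camera, pose, obs_3d, strict=False)
        return np.nan_to_num(uv - obs_2d, nan=1e3).ravel()

    def residuals(x):
        res = reproj(x)
        if center_prior is not None:
            c0, sigma = center_prior
            pose = ViewPose(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])
            res = np.concatenate([res, (pose.camera_center - c0) / sigma])
        return res

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=2000)
    pose = ViewPose(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])
    rmse = float(np.sqrt(np.mean(reproj(sol.x) ** 2) * 2.0))  # per-point px
    return pose, rmse


def _initial_candidates(obs_3d: np.ndarray, obs_2d: np.ndarray, camera: CameraModel) -> list[ViewPose]:
    """Coarse starting poses: camera on a sphere around the points' centroid."""
    center = obs_3d.mean(axis=0)
    spread3 = max(np.linalg.norm(obs_3d - center, axis=1).max(), 1e-3)
    spread2 = max(np.linalg.norm(obs_2d - obs_2d.mean(axis=0), axis=1).max(), 1.0)
    f = 0.5 * (camera.focal[0] + camera.focal[1])
    dist = np.clip(f * spread3 / spread2, 0.05, 50.0)
    dirs = []
    for v in ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]):
        dirs.append(np.asarray(v, dtype=np.float64))
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                dirs.append(np.array([sx, sy, sz]) / np.sqrt(3.0))
    from .camera import look_at_pose

    return [look_at_pose(center + d * dist, center) for d in dirs]


def estimate_pose_from_fiducials(
    observations: list[MarkerObservation],
    camera: CameraModel,
    initial_pose: ViewPose | None = None,
    center_prior_sigma: float | None = None,
) -> tuple[ViewPose, float]:
    """Pose minimizing squared reprojection error of the marker centres.

    With an ``initial_pose`` (e.g. the platform geometry for the view's
    azimuth) a single Levenberg-Marquardt descent is run; otherwise a small
    multi-start over coarse viewing directions picks the best basin.
    ``center_prior_sigma`` (metres) optionally adds a weak penalty pulling
    the camera centre toward the initial pose's: with only three fiducials
    the reprojection problem is exactly determined and its depth direction
    is ill-conditioned, while the rotating-platform protocol fixes the
    camera-to-axis distance -- the prior encodes that knowledge without
    overriding the fiducials in the well-conditioned directions.
    Returns ``(pose, fiducial_rmse_px)``.

    Raises
    ------
    DegenerateMarkersError
        For fewer than 3 observations or collinear marker centres.
    """
    obs_3d = np.asarray([o.mesh_point for o in observations], dtype=np.float64)
    obs_2d = np.asarray([o.image_point for o in observations], dtype=np.float64)
    _check_not_collinear(obs_3d)

    if initial_pose is not None:
        prior = None
        if center_prior_sigma is not None:
            prior = (initial_pose.camera_center, center_prior_sigma)
        return _pnp_refine(obs_3d, obs_2d, camera, initial_pose, center_prior=prior)

    best: tuple[ViewPose, float] | None = None
    for cand in _initial_candidates(obs_3d, obs_2d, camera):
        pose, rmse = _pnp_refine(obs_3d, obs_2d, camera, cand)
        if best is None or rmse < best[1]:
            best = (pose, rmse)
        if best[1] < 1e-8:
            break
    return best


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def mutual_information(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 32,
) -> float:
    """Mutual information (bits) between two images over a pixel mask.

    The joint distribution is a ``bins x bins`` equal-width histogram over
    each image's observed range within the mask.  MI is symmetric,
    non-negative, and equals the marginal entropy when the images are
    identical.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    av, bv = a[mask], b[mask]
    if av.size == 0:
        raise ValueError("mutual information over an empty mask")
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(pa, pb)
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def _shading_image(
    mesh: LimbMesh, camera: CameraModel, pose: ViewPose
) -> tuple[np.ndarray, np.ndarray]:
    shade = lambert_shading(mesh.vertices, mesh.normals, pose.camera_center)
    img, _, face_id = render_attribute(
        camera, pose, mesh.vertices, mesh.faces, shade, background=0.0
    )
    return img, face_id >= 0


def refine_pose(
    initial: ViewPose,
    frame: ThermalFrame,
    mesh: LimbMesh,
    camera: CameraModel,
    bins: int = 32,
    max_evals: int = 160,
    rot_step: float = 0.01,
    trans_step: float = 0.004,
    fiducial_rmse: float = np.nan,
    n_markers: int = 0,
) -> RegistrationResult:
    """Maximize frame-vs-shading mutual information around ``initial``.

    The MI is evaluated over the whole image so that silhouette alignment is
    rewarded: the rendered background (shading 0) must coincide with the
    thermal background for the two images to predict each other well.
    (Restricting the histogram to the rendered silhouette lets a shifted
    pose capture cold background pixels inside its mask and can *raise* MI
    at misaligned poses.)

    Nelder-Mead explores 6 pose increments (axis-angle radians, translation
    metres) with one restart from the best point; the best pose ever
    evaluated (including the initial one) is returned, so the MI score never
    decreases.  Large initial misalignment (tens of degrees) is outside the
    basin of attraction and simply returns unconverged.
    """
    try:
        img0, mask0 = _shading_image(mesh, camera, initial)
    except Exception as exc:
        raise EmptySilhouetteError(f"initial pose renders no silhouette: {exc}") from exc
    if not mask0.any():
        raise EmptySilhouetteError("initial pose renders no silhouette")

    evals = {"n": 0}
    best = {"x": np.zeros(6), "mi": -np.inf}

    def negative_mi(x):
        evals["n"] += 1
        pose = initial.compose_delta(x[:3], x[3:])
        try:
            img, mask = _shading_image(mesh, camera, pose)
        except Exception:
            return 1e3
        if mask.sum() < 50:
            return 1e3
        mi = mutual_information(frame.values, img, None, bins=bins)
        if mi > best["mi"]:
            best["mi"] = mi
            best["x"] = x.copy()
        return -mi

    mi_initial = -negative_mi(np.zeros(6))

    steps = np.array([rot_step] * 3 + [trans_step] * 3)
    converged = True
    x_start = np.zeros(6)
    for attempt in range(2):
        simplex = np.vstack([x_start, x_start + np.diag(steps)])
        res = minimize(
            negative_mi,
            x_start,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": max_evals // 2,
                "xatol": 1e-4,
                "fatol": 1e-5,
            },
        )
        converged = bool(res.success)
        x_start = best["x"]
        steps = steps / 4.0  # restart tighter around the best point

    final_pose = initial.compose_delta(best["x"][:3], best["x"][3:])
    return RegistrationResult(
        pose=final_pose,
        mi_score=float(best["mi"]),
        fiducial_rmse=fiducial_rmse,
        converged=converged,
        mi_initial=float(mi_initial),
        n_markers=n_markers,
    )


def register_view(
    frame: ThermalFrame,
    mesh: LimbMesh,
    marker_centers: np.ndarray,
    marker_normals: np.ndarray | None,
    camera: CameraModel,
    nominal_pose: ViewPose,
    marker_temperature: float = MARKER_TEMPERATURE,
    tolerance: float = 1.0,
    refine: bool = True,
    center_prior_sigma: float | None = 0.02,
) -> RegistrationResult:
    """Full per-view registration: detect, match, PnP, then MI refinement.

    Falls back to the nominal platform pose (flagged unconverged) when fewer
    than three fiducials can be matched in the frame.
    """
    blobs = detect_marker_blobs(frame, marker_temperature, tolerance)
    obs = match_blobs_to_markers(
        blobs, marker_centers, marker_normals, camera, nominal_pose
    )
    if len(obs) >= 3:
        pose0, rmse = estimate_pose_from_fiducials(
            obs, camera, initial_pose=nominal_pose, center_prior_sigma=center_prior_sigma
        )
    else:
        pose0, rmse = nominal_pose, np.nan
    if not refine:
        return RegistrationResult(
            pose=pose0, mi_score=np.nan, fiducial_rmse=rmse,
            converged=len(obs) >= 3, n_markers=len(obs),
        )
    result = refine_pose(
        pose0, frame, mesh, camera, fiducial_rmse=rmse, n_markers=len(obs)
    )
    if len(obs) < 3:
        result.converged = False
    return result
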