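"""Synthetic limb scenes with ground truth for end-to-end validation.

Real acquisitions image a transtibial residual limb standing on a rotating
platform: an infrared camera 120 cm from the limb axis collects 7 views in
45-degree steps while small hollow-cube fiducial markers on the skin stay
visible both thermally (ambient air keeps them colder than skin) and
geometrically (they bump out of the 3D scan).  This module fabricates that
whole situation with known ground truth: a tapered-cone limb capped by a
hemisphere, cube-on-disc fiducials, smooth skin-temperature fields with
localized hot spots for a rest and a post-walk condition, and thermal frames
rendered through the calibrated camera model with sensor noise at the
camera's NETD.

Every quantity downstream modules estimate -- camera poses, marker centres,
per-vertex temperatures -- is recorded exactly, so registration, texturing
and differential-map errors can be measured rather than eyeballed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh

from .camera import CameraModel, ViewPose, look_at_pose
from .mesh import LimbMesh
from .raster import render_attribute
from .thermal_io import ThermalFrame, AcquisitionMetadata

#: Fixed temperature (degC) at which fiducial cubes render; below the skin
#: band so markers saturate to the first colormap colour and stay identical
#: across conditions.
MARKER_TEMPERATURE = 26.0
#: Laboratory ambient temperature (degC); thermal background of every frame.
AMBIENT_TEMPERATURE = 23.0
#: Sensor noise floor (NETD), degC standard deviation per pixel.
SENSOR_NETD = 0.07
#: Camera distance from the limb axis, metres.
CAMERA_DISTANCE = 1.20


class MarkerPlacementError(ValueError):
    """Two fiducials overlap on the limb surface."""


class TemperatureRangeError(ValueError):
    """A composed skin temperature falls outside the colormap anchor span."""


@dataclass(frozen=True)
class LimbSpec:
    """Geometry of the synthetic residual limb.

    A tapered cone stands on the z axis from the distal junction (z = 0,
    radius ``distal_radius``) up to the proximal rim (z = ``length``, radius
    ``proximal_radius``); a hemisphere of radius ``distal_radius`` caps the
    distal end below z = 0.
    """

    length: float = 0.20            # m
    proximal_radius: float = 0.05   # m
    distal_radius: float = 0.04     # m
    mesh_resolution: int = 16000    # target vertex count

    def __post_init__(self) -> None:
        if min(self.length, self.proximal_radius, self.distal_radius) <= 0:
            raise ValueError("limb dimensions must be positive")

    def radius_at(self, z: float | np.ndarray) -> float | np.ndarray:
        """Cone radius at height z (m)."""
        return self.distal_radius + (self.proximal_radius - self.distal_radius) * (
            np.asarray(z) / self.length
        )

    def surface_point(self, axial_fraction: float, azimuth_deg: float) -> np.ndarray:
        z = axial_fraction * self.length
        r = float(self.radius_at(z))
        a = np.deg2rad(azimuth_deg)
        return np.array([r * np.cos(a), r * np.sin(a), z])


@dataclass(frozen=True)
class MarkerSpec:
    """Cube-on-disc fiducial geometry (mm) and surface placements.

    ``placements`` is a list of (axial fraction in [0, 1], azimuth degrees);
    defaults spread five markers around the limb so at least three fall
    inside every 45-degree view.
    """

    cube_edge: float = 5.0        # mm
    base_diameter: float = 14.0   # mm
    base_thickness: float = 0.5   # mm
    placements: tuple[tuple[float, float], ...] = (
        (0.25, 0.0),
        (0.55, 72.0),
        (0.80, 144.0),
        (0.40, 216.0),
        (0.70, 288.0),
    )

    @property
    def center_offset(self) -> float:
        """Distance (m) from the skin surface to the cube centre."""
        return (self.base_thickness + self.cube_edge / 2.0) / 1000.0


@dataclass
class TemperatureField:
    """Skin-temperature model: a base level plus Gaussian bumps.

    Each hot (or cold, for negative peaks) spot is ``(surface point xyz m,
    peak delta degC, gaussian radius m)``; the field at a vertex is
    ``base + sum peak_i * exp(-d_i^2 / (2 radius_i^2))`` with d the Euclidean
    (chord) distance to the spot centre -- a good geodesic proxy for spot
    radii much smaller than the limb radius.
    """

    base_temperature: float
    hot_spots: list[tuple[np.ndarray, float, float]] = field(default_factory=list)
    condition_label: str = "rest"

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        t = np.full(len(points), self.base_temperature, dtype=np.float64)
        for center, peak, radius in self.hot_spots:
            d2 = ((points - np.asarray(center)[None, :]) ** 2).sum(axis=1)
            t += peak * np.exp(-d2 / (2.0 * radius**2))
        return t


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def _limb_body(spec: LimbSpec, seed: int) -> trimesh.Trimesh:
    """Watertight cone + hemisphere + proximal cap, ~resolution vertices."""
    # Reserve a little of the vertex budget for the fiducials.
    target = max(spec.mesh_resolution, 500)
    area_cone = np.pi * (spec.proximal_radius + spec.distal_radius) * spec.length
    area_hemi = 2.0 * np.pi * spec.distal_radius**2
    h = np.sqrt((area_cone + area_hemi) / target)  # target vertex spacing

    mean_r = 0.5 * (spec.proximal_radius + spec.distal_radius)
    n_theta = max(int(round(2.0 * np.pi * mean_r / h)), 12)
    n_z = max(int(round(spec.length / h)) + 1, 4)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)

    rng = np.random.default_rng(seed)

    verts = []
    # Cone rings, distal (z=0) to proximal (z=length).
    zs = np.linspace(0.0, spec.length, n_z)
    for z in zs:
        r = spec.radius_at(z)
        jitter = rng.normal(0.0, 1e-4, n_theta)  # 0.1 mm radial scan noise
        verts.append(
            np.column_stack(
                [
                    (r + jitter) * np.cos(theta),
                    (r + jitter) * np.sin(theta),
                    np.full(n_theta, z),
                ]
            )
        )
    # Hemisphere rings below z=0 (polar angle from equator to pole).
    n_phi = max(int(round((np.pi / 2.0) * spec.distal_radius / h)), 3)
    phis = np.linspace(0.0, np.pi / 2.0, n_phi + 1)[1:-1]
    for phi in phis:
        r = spec.distal_radius * np.cos(phi)
        z = -spec.distal_radius * np.sin(phi)
        verts.append(
            np.column_stack(
                [r * np.cos(theta), r * np.sin(theta), np.full(n_theta, z)]
            )
        )
    rings = len(verts)
    flat = np.concatenate(verts)
    pole = np.array([[0.0, 0.0, -spec.distal_radius]])
    apex = np.array([[0.0, 0.0, spec.length]])
    all_verts = np.concatenate([flat, pole, apex])
    pole_idx = len(flat)
    apex_idx = len(flat) + 1

    # Ring order along the surface: hemisphere pole -> equator -> proximal rim.
    ring_order = list(range(rings - 1, n_z - 1, -1)) + list(range(n_z))

    faces = []
    for a, b in zip(ring_order[:-1], ring_order[1:]):
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            va, va2 = a * n_theta + j, a * n_theta + j2
            vb, vb2 = b * n_theta + j, b * n_theta + j2
            faces.append([va, vb, vb2])
            faces.append([va, vb2, va2])
    bottom = ring_order[0]
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        faces.append([pole_idx, bottom * n_theta + j, bottom * n_theta + j2])
    top = ring_order[-1]
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        faces.append([apex_idx, top * n_theta + j2, top * n_theta + j])

    body = trimesh.Trimesh(all_verts, np.asarray(faces), process=False)
    if body.volume < 0:
        body.invert()
    return body


def _marker_geometry(spec: MarkerSpec, surface_point: np.ndarray, radial_dir: np.ndarray,
                     subdivide: int = 1) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Closed cube + base-disc geometry, slightly embedded in the skin.

    Returns the mesh and a boolean per-vertex mask marking the cube (the
    thermally cold part; the thin base disc sits in full skin contact and
    tracks skin temperature).
    """
    edge = spec.cube_edge / 1000.0
    thick = spec.base_thickness / 1000.0
    embed = 0.3e-3  # sink the base into the skin to avoid coplanar faces

    base = trimesh.creation.cylinder(
        radius=spec.base_diameter / 2000.0, height=thick + embed, sections=24
    )
    base.apply_translation([0.0, 0.0, (thick + embed) / 2.0 - embed])
    cube = trimesh.creation.box(extents=[edge, edge, edge])
    for _ in range(subdivide):
        cube = trimesh.Trimesh(*trimesh.remesh.subdivide(cube.vertices, cube.faces), process=False)
    cube.apply_translation([0.0, 0.0, thick + edge / 2.0])

    marker = trimesh.util.concatenate([base, cube])
    cube_mask = np.zeros(len(marker.vertices), dtype=bool)
    cube_mask[len(base.vertices):] = True
    # Rotate local +z onto the outward radial direction.
    z = np.array([0.0, 0.0, 1.0])
    rot = trimesh.geometry.align_vectors(z, radial_dir)
    marker.apply_transform(rot)
    marker.apply_translation(surface_point)
    return marker, cube_mask


def make_limb_mesh(
    spec: LimbSpec = LimbSpec(),
    markers: MarkerSpec = MarkerSpec(),
    seed: int = 0,
) -> tuple[LimbMesh, np.ndarray]:
    """Build the limb mesh with fiducials; returns (mesh, marker_centres).

    The mesh's ``marker_id`` attribute is -1 on skin and the marker index on
    fiducial geometry.  Marker centres (cube centres, metres) are the ground
    truth used for registration assessment.

    Raises
    ------
    MarkerPlacementError
        If two placements are closer than one base diameter.
    """
    body = _limb_body(spec, seed)

    surface_pts = [spec.surface_point(a, az) for a, az in markers.placements]
    for i in range(len(surface_pts)):
        for j in range(i + 1, len(surface_pts)):
            if np.linalg.norm(surface_pts[i] - surface_pts[j]) < markers.base_diameter / 1000.0:
                raise MarkerPlacementError(
                    f"markers {i} and {j} overlap (closer than one base diameter)"
                )

    pieces = [body]
    marker_ids = [np.full(len(body.vertices), -1, dtype=np.int64)]
    cube_masks = [np.zeros(len(body.vertices), dtype=bool)]
    centers = []
    for k, p in enumerate(surface_pts):
        radial = np.array([p[0], p[1], 0.0])
        radial /= np.linalg.norm(radial)
        geom, cube_mask = _marker_geometry(markers, p, radial)
        pieces.append(geom)
        marker_ids.append(np.full(len(geom.vertices), k, dtype=np.int64))
        cube_masks.append(cube_mask)
        centers.append(p + radial * markers.center_offset)

    merged = trimesh.util.concatenate(pieces)
    marker_id = np.concatenate(marker_ids)
    verts = np.asarray(merged.vertices)
    # Body vertices hidden under a marker base are never seen by the scanner
    # (the fiducial replaces them in a real scan); tag them as marker
    # geometry so they stay out of skin statistics.
    body_sel = marker_id < 0
    for k, p in enumerate(surface_pts):
        under = np.linalg.norm(verts - p[None, :], axis=1) < markers.base_diameter / 2000.0
        marker_id[body_sel & under] = k
    mesh = LimbMesh(
        verts,
        np.asarray(merged.faces),
        marker_id=marker_id,
        extra={"marker_cube": np.concatenate(cube_masks).astype(np.float64)},
    )
    return mesh, np.asarray(centers)


# ---------------------------------------------------------------------------
# Temperature fields
# ---------------------------------------------------------------------------

def default_fields(spec: LimbSpec = LimbSpec()) -> tuple[TemperatureField, TemperatureField]:
    """The two study conditions the generator emulates.

    Rest: 31 degC baseline with a cooler distal end (about 30 degC at the
    tip).  Post-walk: uniformly warmer (32.5 degC) with peri-knee hot spots
    reaching about 36 degC, so the differential map shows 1.5-3.5 degC of
    walking-induced warming everywhere except at the fiducials.
    """
    tip = np.array([0.0, 0.0, -spec.distal_radius])
    rest = TemperatureField(
        base_temperature=31.0,
        hot_spots=[(tip, -1.0, 0.05)],
        condition_label="rest",
    )
    post = TemperatureField(
        base_temperature=32.5,
        hot_spots=[
            (spec.surface_point(0.90, 30.0), 3.5, 0.025),
            (spec.surface_point(0.85, 200.0), 2.5, 0.030),
            (spec.surface_point(0.30, 120.0), 1.5, 0.030),
            (tip, -0.8, 0.05),
        ],
        condition_label="post_walk",
    )
    return rest, post


def make_temperature_fields(
    mesh: LimbMesh,
    rest: TemperatureField,
    post_walk: TemperatureField,
    marker_temperature: float = MARKER_TEMPERATURE,
    t_low: float = 28.0,
    t_high: float = 37.0,
) -> dict[str, np.ndarray]:
    """Per-vertex ground-truth temperatures for both conditions.

    Skin (and marker base-disc) vertices get the composed field value --
    the thin base sits in full skin contact and equilibrates with it.  The
    hollow-cube vertices are pinned at ``marker_temperature`` in both
    conditions (ambient air flows through the cube), so the cube's
    differential temperature is exactly zero: that is the property the
    registration accuracy assessment exploits.

    Raises
    ------
    TemperatureRangeError
        If a composed non-cube value leaves [t_low, t_high].
    """
    out = {}
    if mesh.extra.get("marker_cube") is not None:
        cube = mesh.extra["marker_cube"] > 0.5
    elif mesh.marker_id is not None:
        cube = mesh.marker_id >= 0
    else:
        cube = np.zeros(mesh.n_vertices, dtype=bool)
    for name, fld in (("rest", rest), ("post_walk", post_walk)):
        t = fld.evaluate(mesh.vertices)
        if t[~cube].min() < t_low or t[~cube].max() > t_high:
            raise TemperatureRangeError(
                f"{name} field spans [{t[~cube].min():.2f}, {t[~cube].max():.2f}] degC, "
                f"outside [{t_low}, {t_high}]"
            )
        t[cube] = marker_temperature
        out[name] = t
    return out


# ---------------------------------------------------------------------------
# Acquisition geometry and rendering
# ---------------------------------------------------------------------------

def platform_poses(
    n_views: int = 7,
    distance: float = CAMERA_DISTANCE,
    target_height: float = 0.10,
    azimuth_step: float = 45.0,
) -> list[ViewPose]:
    """Camera poses of the rotating-platform acquisition.

    The camera stays ``distance`` metres from the limb axis at the height of
    the limb midpoint; successive views step ``azimuth_step`` degrees around
    the axis (7 views cover 0-270 degrees).
    """
    poses = []
    target = np.array([0.0, 0.0, target_height])
    for i in range(n_views):
        a = np.deg2rad(i * azimuth_step)
        eye = np.array([distance * np.cos(a), distance * np.sin(a), target_height])
        poses.append(look_at_pose(eye, target))
    return poses


def view_labels(n_views: int = 7, azimuth_step: float = 45.0) -> list[str]:
    return [f"az{int(round(i * azimuth_step)):03d}" for i in range(n_views)]


def render_thermal_frame(
    mesh: LimbMesh,
    vertex_temps: np.ndarray,
    camera: CameraModel,
    pose: ViewPose,
    noise_sd: float = SENSOR_NETD,
    ambient: float = AMBIENT_TEMPERATURE,
    view_id: str = "view",
    rng: np.random.Generator | None = None,
    condition_label: str | None = None,
) -> ThermalFrame:
    """Render one thermal frame of the scene through the distorted camera.

    Visible-surface temperature per pixel (perspective-correct barycentric
    interpolation), background at the ambient temperature, plus additive
    Gaussian sensor noise of ``noise_sd`` degC.
    """
    image, _, _ = render_attribute(
        camera, pose, mesh.vertices, mesh.faces, vertex_temps, background=ambient
    )
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        image = image + rng.normal(0.0, noise_sd, image.shape)
    meta = AcquisitionMetadata(
        ambient_temperature=ambient,
        camera_distance=CAMERA_DISTANCE * 100.0,
        condition_label=condition_label,
    )
    return ThermalFrame(values=image, view_id=view_id, metadata=meta)


# ---------------------------------------------------------------------------
# Whole-scene assembly
# ---------------------------------------------------------------------------

@dataclass
class SceneGroundTruth:
    """Everything the pipeline is supposed to recover, known exactly."""

    mesh: LimbMesh
    marker_centers: np.ndarray           # (n_markers, 3) m
    marker_normals: np.ndarray           # (n_markers, 3) outward radial
    poses: list[ViewPose]                # true per-view poses (with wobble)
    camera: CameraModel
    temperatures: dict[str, np.ndarray]  # condition -> (n_vertices,)
    frames: dict[str, list[ThermalFrame]]
    seed: int = 0
    nominal_poses: list[ViewPose] | None = None  # ideal platform geometry

    def save(self, out_dir: str | Path) -> None:
        """Write the dataset: PLY mesh, thermal CSVs, camera and truth JSON."""
        from .thermal_io import write_thermal_frame

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mesh = self.mesh.copy()
        for cond, temps in self.temperatures.items():
            mesh.extra[f"gt_{cond}"] = temps
        mesh.save_ply(out / "limb.ply")
        self.camera.to_json(out / "camera.json")
        truth = {
            "seed": self.seed,
            "marker_centers_m": self.marker_centers.tolist(),
            "marker_normals": self.marker_normals.tolist(),
            "marker_temperature_c": MARKER_TEMPERATURE,
            "poses": [p.to_dict() for p in self.poses],
            "nominal_poses": [
                p.to_dict() for p in (self.nominal_poses or self.poses)
            ],
            "view_ids": [f.view_id for f in next(iter(self.frames.values()))],
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
        for cond, frames in self.frames.items():
            cdir = out / cond
            cdir.mkdir(exist_ok=True)
            for f in frames:
                write_thermal_frame(f, cdir / f"{f.view_id}.csv")


#: Platform repeatability emulated by the scene: per-view orientation and
#: placement wobble of the true camera-to-limb pose around the nominal
#: geometry (rotation sd radians ~0.5 deg, translation sd metres).
POSE_WOBBLE_ROT_SD = np.deg2rad(0.5)
POSE_WOBBLE_TRANS_SD = 2e-3


def make_scene(
    limb: LimbSpec = LimbSpec(),
    markers: MarkerSpec = MarkerSpec(),
    camera: CameraModel | None = None,
    n_views: int = 7,
    noise_sd: float = SENSOR_NETD,
    seed: int = 0,
    pose_wobble: bool = True,
) -> SceneGroundTruth:
    """Assemble the full synthetic acquisition: mesh, fields, frames, truth.

    The geometry is controlled by ``seed``; frame noise uses an independent
    stream derived from it, so geometry is reproducible even when the noise
    level changes.  With ``pose_wobble`` (the default) each true view pose
    deviates from the ideal platform geometry by a small seeded rotation and
    translation, emulating platform step error and imperfect centring of
    the limb on the rotation axis -- registration must actually recover the
    true poses rather than echo the nominal ones.
    """
    camera = camera or CameraModel(radial=(-0.1004, -1.0318))
    mesh, centers = make_limb_mesh(limb, markers, seed=seed)
    normals = centers - np.column_stack([np.zeros((len(centers), 2)), centers[:, 2]])
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    rest, post = default_fields(limb)
    temps = make_temperature_fields(mesh, rest, post)
    nominal = platform_poses(n_views, target_height=limb.length / 2.0)
    if pose_wobble:
        wobble_rng = np.random.default_rng(np.random.SeedSequence([seed, 271]))
        poses = [
            p.compose_delta(
                wobble_rng.normal(0.0, POSE_WOBBLE_ROT_SD, 3),
                wobble_rng.normal(0.0, POSE_WOBBLE_TRANS_SD, 3),
            )
            for p in nominal
        ]
    else:
        poses = list(nominal)
    labels = view_labels(n_views)

    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    frames: dict[str, list[ThermalFrame]] = {}
    for cond in ("rest", "post_walk"):
        frames[cond] = [
            render_thermal_frame(
                mesh, temps[cond], camera, pose,
                noise_sd=noise_sd, view_id=label, rng=noise_rng, condition_label=cond,
            )
            for pose, label in zip(poses, labels)
        ]
    return SceneGroundTruth(
        mesh=mesh,
        marker_centers=centers,
        marker_normals=normals,
        poses=poses,
        camera=camera,
        temperatures=temps,
        frames=frames,
        seed=seed,
        nominal_poses=nominal,
    )
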