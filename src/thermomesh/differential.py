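"""Differential 3D thermal maps and intrinsic registration-accuracy metrics.

Once both acquisition conditions (say post-walk and rest) are textured onto
the *same* limb mesh, the per-vertex temperature difference summarizes the
physiological response in a single 3D map.  The fiducial cubes double as an
intrinsic quality control: their temperature is the same in both conditions,
so each marker should produce a near-zero patch ("halo") in the differential
map centred on the marker -- any displacement of that halo measures the
combined registration error of the two conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .colormap import jet_channels
from .mesh import LimbMesh, vertex_adjacency


@dataclass
class DifferentialMap:
    """Per-vertex temperature difference between two conditions on one mesh."""

    mesh: LimbMesh
    delta_t: np.ndarray          # (n,) degC, NaN where either input missing
    colors: np.ndarray           # (n, 3) uint8 jet over [min dT, max dT]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.delta_t)


@dataclass
class RegistrationErrorStats:
    """Marker-halo misalignment summary, millimetres."""

    per_marker: list[float]      # one distance per marker with a halo
    missing_markers: int = 0     # markers with no detectable halo

    @property
    def median(self) -> float:
        return float(np.median(self.per_marker))

    @property
    def sd(self) -> float:
        if len(self.per_marker) < 2:
            return 0.0
        return float(np.std(self.per_marker, ddof=1))

    @property
    def range(self) -> tuple[float, float]:
        return (float(np.min(self.per_marker)), float(np.max(self.per_marker)))

    def to_dict(self) -> dict:
        return {
            "median_mm": self.median,
            "sd_mm": self.sd,
            "min_mm": self.range[0],
            "max_mm": self.range[1],
            "per_marker_mm": [float(v) for v in self.per_marker],
            "missing_markers": self.missing_markers,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")


def differential_map(mesh_a: LimbMesh, mesh_b: LimbMesh) -> DifferentialMap:
    """Per-vertex ``T_a - T_b`` between two texturings of the same mesh.

    Both meshes must have identical vertex counts and ordering (the workflow
    textures both conditions onto one 3D model).  Vertices missing (NaN) in
    either input are missing in the output.  Colours code the difference
    with the jet map stretched linearly from the observed minimum (first
    colour) to the observed maximum (last colour).
    """
    if mesh_a.n_vertices != mesh_b.n_vertices:
        raise ValueError(
            f"vertex count mismatch: {mesh_a.n_vertices} vs {mesh_b.n_vertices}"
        )
    if mesh_a.vertex_temperature is None or mesh_b.vertex_temperature is None:
        raise ValueError("both meshes need vertex temperatures")
    if not np.allclose(mesh_a.vertices, mesh_b.vertices, atol=1e-9):
        raise ValueError("meshes have different geometry; texture one model twice")

    delta = mesh_a.vertex_temperature - mesh_b.vertex_temperature
    valid = np.isfinite(delta)
    colors = np.zeros((len(delta), 3), dtype=np.uint8)
    if valid.any():
        lo, hi = np.min(delta[valid]), np.max(delta[valid])
        span = hi - lo if hi > lo else 1.0
        x = np.clip((delta[valid] - lo) / span, 0.0, 1.0)
        colors[valid] = np.floor(jet_channels(x) * 255.0 + 0.5).astype(np.uint8)

    out = mesh_a.copy()
    out.vertex_temperature = None
    out.vertex_rgb = colors
    out.extra = dict(mesh_a.extra)
    out.extra["delta_t"] = delta
    return DifferentialMap(mesh=out, delta_t=delta, colors=colors)


def marker_halo_error(
    diff: DifferentialMap,
    marker_centers: np.ndarray,
    marker_normals: np.ndarray | None = None,
    search_radius: float = 0.015,
    zero_tolerance: float = 0.3,
    min_halo_vertices: int = 3,
) -> RegistrationErrorStats:
    """Misalignment of each marker's near-zero halo in the differential map.

    For each marker, vertices within ``search_radius`` (m) of its centre
    whose |dT| is at most ``zero_tolerance`` (degC) form the halo; the
    distance (mm) from the marker centre to the halo centroid is that
    marker's misalignment.  When the marker's outward normal is supplied the
    centre-to-centroid offset is projected onto the plane perpendicular to
    it: the halo lies on the limb surface while the centre sits mid-cube a
    few millimetres above it, and only the in-surface component measures
    registration error.  Markers with fewer than ``min_halo_vertices`` halo
    vertices are counted as missing and excluded from the statistics.
    """
    centers = np.atleast_2d(np.asarray(marker_centers, dtype=np.float64))
    if len(centers) == 0:
        raise ValueError("at least one marker centre is required")
    verts = diff.mesh.vertices
    good = diff.valid & (np.abs(diff.delta_t) <= zero_tolerance)

    distances = []
    missing = 0
    for k, c in enumerate(centers):
        near = np.linalg.norm(verts - c[None, :], axis=1) <= search_radius
        halo = near & good
        if halo.sum() < min_halo_vertices:
            missing += 1
            continue
        centroid = verts[halo].mean(axis=0)
        offset = centroid - c
        if marker_normals is not None:
            n = np.asarray(marker_normals[k], dtype=np.float64)
            n = n / np.linalg.norm(n)
            offset = offset - n * (offset @ n)
        distances.append(float(np.linalg.norm(offset) * 1000.0))
    if not distances:
        raise ValueError("no marker produced a detectable halo")
    return RegistrationErrorStats(per_marker=distances, missing_markers=missing)


def summarize_hotspots(
    mesh: LimbMesh, threshold: float, temperatures: np.ndarray | None = None
) -> list[dict]:
    """Connected warm regions above ``threshold`` degC.

    Returns one record per connected component of supra-threshold vertices:
    component id, vertex count, surface area (m^2, one third of each
    incident face's area per vertex) and peak temperature.
    """
    t = temperatures if temperatures is not None else mesh.vertex_temperature
    if t is None:
        raise ValueError("mesh has no temperatures")
    hot = np.isfinite(t) & (t > threshold)
    if not hot.any():
        return []

    adj = vertex_adjacency(mesh.faces, mesh.n_vertices)
    sub = adj[hot][:, hot]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)

    # one-third face-area accumulation per vertex
    tri = mesh.vertices[mesh.faces]
    face_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    vert_area = np.zeros(mesh.n_vertices)
    for i in range(3):
        np.add.at(vert_area, mesh.faces[:, i], face_area / 3.0)

    hot_idx = np.flatnonzero(hot)
    out = []
    for comp in range(n_comp):
        sel = hot_idx[labels == comp]
        out.append(
            {
                "component": comp,
                "n_vertices": int(len(sel)),
                "area_m2": float(vert_area[sel].sum()),
                "peak_c": float(t[sel].max()),
            }
        )
    out.sort(key=lambda r: -r["n_vertices"])
    for i, r in enumerate(out):
        r["component"] = i
    return out
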