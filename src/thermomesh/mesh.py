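"""Triangle-mesh container for limb surfaces with thermal attributes.

A :class:`LimbMesh` is a triangle mesh (metres) that may carry, per vertex:
8-bit RGB colour (from texturing), a temperature in degC (from colour
decoding; NaN marks vertices invisible in every view), and a fiducial-marker
id (-1 for skin).  Meshes serialize to PLY -- ASCII or binary little-endian
-- with the colours as uchar red/green/blue and each scalar attribute as a
float property, so results open directly in standard mesh viewers.

trimesh handles the geometry export; reading goes through a small PLY parser
here because custom scalar vertex properties must survive the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import trimesh

#: Reserved colour marking a vertex that no view could texture.
SENTINEL_RGB = (0, 0, 0)


@dataclass
class LimbMesh:
    """Triangle mesh with optional per-vertex thermal attributes."""

    vertices: np.ndarray                    # (n, 3) float64, metres
    faces: np.ndarray                       # (m, 3) int64
    normals: np.ndarray | None = None       # (n, 3) unit outward
    vertex_rgb: np.ndarray | None = None    # (n, 3) uint8
    vertex_temperature: np.ndarray | None = None  # (n,) degC, NaN = missing
    marker_id: np.ndarray | None = None     # (n,) int, -1 = skin
    extra: dict = dc_field(default_factory=dict)  # other scalar properties

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.normals is None:
            self.normals = vertex_normals(self.vertices, self.faces)
        else:
            self.normals = np.asarray(self.normals, dtype=np.float64)
        for name in ("vertex_rgb", "vertex_temperature", "marker_id"):
            val = getattr(self, name)
            if val is not None and len(val) != len(self.vertices):
                raise ValueError(f"{name} length {len(val)} != vertex count {len(self.vertices)}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, **kwargs) -> "LimbMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), **kwargs)

    def copy(self) -> "LimbMesh":
        return LimbMesh(
            self.vertices.copy(),
            self.faces.copy(),
            normals=self.normals.copy(),
            vertex_rgb=None if self.vertex_rgb is None else self.vertex_rgb.copy(),
            vertex_temperature=(
                None if self.vertex_temperature is None else self.vertex_temperature.copy()
            ),
            marker_id=None if self.marker_id is None else self.marker_id.copy(),
            extra={k: v.copy() for k, v in self.extra.items()},
        )

    # -- serialization ----------------------------------------------------

    def save_ply(self, path: str | Path, encoding: str = "binary_little_endian") -> None:
        """Write the mesh and all present attributes as PLY."""
        tm = self.to_trimesh()
        if self.vertex_rgb is not None:
            rgba = np.column_stack(
                [self.vertex_rgb, np.full(self.n_vertices, 255, dtype=np.uint8)]
            )
            tm.visual.vertex_colors = rgba
        if self.vertex_temperature is not None:
            tm.vertex_attributes["temperature"] = self.vertex_temperature.astype(np.float32)
        if self.marker_id is not None:
            tm.vertex_attributes["marker_id"] = self.marker_id.astype(np.float32)
        for name, arr in self.extra.items():
            tm.vertex_attributes[name] = np.asarray(arr, dtype=np.float32)
        data = trimesh.exchange.ply.export_ply(tm, encoding=encoding)
        Path(path).write_bytes(data)

    @classmethod
    def load_ply(cls, path: str | Path) -> "LimbMesh":
        verts, faces, props = read_ply(path)
        rgb = None
        if all(k in props for k in ("red", "green", "blue")):
            rgb = np.column_stack([props.pop("red"), props.pop("green"), props.pop("blue")])
            rgb = rgb.astype(np.uint8)
            props.pop("alpha", None)
        temp = props.pop("temperature", None)
        marker = props.pop("marker_id", None)
        for k in ("x", "y", "z", "nx", "ny", "nz"):
            props.pop(k, None)
        return cls(
            verts,
            faces,
            vertex_rgb=rgb,
            vertex_temperature=None if temp is None else temp.astype(np.float64),
            marker_id=None if marker is None else marker.astype(np.int64),
            extra={k: v.astype(np.float64) for k, v in props.items()},
        )


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex normals, unit length."""
    tm = trimesh.Trimesh(vertices, faces, process=False)
    n = np.asarray(tm.vertex_normals, dtype=np.float64).copy()
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norm, 1e-12)


def vertex_adjacency(faces: np.ndarray, n_vertices: int):
    """Sparse vertex-vertex adjacency (CSR boolean) from triangle faces."""
    from scipy import sparse

    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.ones(len(rows), dtype=bool)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_vertices, n_vertices))


# ---------------------------------------------------------------------------
# PLY parsing (ascii / binary little-endian, triangular faces)
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read a PLY mesh, returning vertices, faces and all vertex properties.

    Handles ASCII and binary little-endian files with triangular faces; every
    scalar vertex property (colour channels, temperature, ...) is returned in
    the properties dict keyed by its PLY name.
    """
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header\n")
    if end < 0:
        raise ValueError(f"{path}: not a PLY file (missing end_header)")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header\n"):]

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for line in header:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if tok[1] == "list":
                elements[-1][2].append((tok[-1], f"list:{tok[2]}:{tok[3]}"))
            else:
                elements[-1][2].append((tok[-1], _PLY_TYPES[tok[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")

    verts = faces = None
    props: dict[str, np.ndarray] = {}
    if fmt == "ascii":
        lines = body.decode("ascii").splitlines()
        cursor = 0
        for name, count, fields in elements:
            chunk = lines[cursor : cursor + count]
            cursor += count
            if name == "vertex":
                table = np.array([ln.split() for ln in chunk], dtype=np.float64)
                for j, (pname, _) in enumerate(fields):
                    props[pname] = table[:, j]
            elif name == "face":
                rows = [ln.split() for ln in chunk]
                if any(int(r[0]) != 3 for r in rows):
                    raise ValueError("only triangular faces are supported")
                faces = np.array([r[1:4] for r in rows], dtype=np.int64)
    else:
        offset = 0
        for name, count, fields in elements:
            if name == "vertex":
                dt = np.dtype([(p, "<" + t) for p, t in fields])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                for pname, _ in fields:
                    props[pname] = arr[pname].astype(np.float64)
            elif name == "face":
                spec = fields[0][1]
                _, count_t, idx_t = spec.split(":")
                dt = np.dtype(
                    [("n", "<" + _PLY_TYPES[count_t]), ("idx", "<" + _PLY_TYPES[idx_t], (3,))]
                )
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                if count and not np.all(arr["n"] == 3):
                    raise ValueError("only triangular faces are supported")
                faces = arr["idx"].astype(np.int64)
            else:
                raise ValueError(f"unsupported PLY element {name!r} in binary file")

    if not all(k in props for k in ("x", "y", "z")):
        raise ValueError(f"{path}: PLY has no vertex coordinates")
    verts = np.column_stack([props["x"], props["y"], props["z"]])
    if faces is None:
        faces = np.empty((0, 3), dtype=np.int64)
    return verts, faces, props
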