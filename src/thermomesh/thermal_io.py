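"""Reading, writing and validation of thermal raster frames.

An infrared camera exports each acquisition as a table of per-pixel skin
temperatures in degrees Celsius.  The sensor used throughout this package is a
320 x 240 microbolometer, so a valid frame is exactly 240 rows by 320 columns.
Exports from vendor software differ in delimiter (comma, semicolon, tab) and
in decimal convention (dot or comma), so the reader auto-detects both.

Acquisition conditions (ambient temperature, relative humidity, emissivity,
camera distance, rest/walk protocol timings) are carried as metadata in a JSON
sidecar next to each raster file.  They are recorded for traceability only and
never enter any computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

#: Sensor raster size (rows, columns).
FRAME_SHAPE = (240, 320)
#: Measurable temperature range of the sensor, degC.
SENSOR_RANGE = (-20.0, 120.0)


class FrameDimensionError(ValueError):
    """Raster does not have the expected 240 x 320 shape."""


class FrameParseError(ValueError):
    """A cell of the raster could not be parsed as a number."""


class FrameRangeError(ValueError):
    """A temperature lies outside the sensor's measurable range."""


@dataclass
class AcquisitionMetadata:
    """Ambient and protocol conditions under which a frame was acquired.

    All fields are record-only: they document the acquisition and are never
    used in any downstream computation.
    """

    ambient_temperature: float = 23.0   # degC
    relative_humidity: float = 58.5     # percent
    emissivity: float = 0.98            # human skin
    camera_distance: float = 120.0      # cm, camera to limb axis
    condition_label: str | None = None  # "rest" or "post_walk"
    rest_minutes: float | None = None
    walk_minutes: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if self.condition_label not in (None, "rest", "post_walk"):
            raise ValueError(
                f"condition_label must be 'rest' or 'post_walk', got {self.condition_label!r}"
            )


@dataclass
class ThermalFrame:
    """One 240 x 320 raster of temperatures in degC plus identification.

    Parameters
    ----------
    values
        Temperature matrix, shape (240, 320), degC.  Row 0 is the top of the
        image, column 0 the left; pixel centers sit at integer coordinates.
    view_id
        Label of the view, e.g. ``"az000"`` or ``"anterior"``.
    timestamp
        Optional ISO-8601 acquisition time.
    metadata
        Acquisition conditions; defaults describe the standard protocol.
    """

    values: np.ndarray
    view_id: str
    timestamp: str | None = None
    metadata: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        validate_frame_values(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def validate_frame_values(values: np.ndarray) -> None:
    """Raise if ``values`` violates any frame invariant.

    Invalid frames are rejected, never silently clipped.
    """
    if values.ndim != 2 or values.shape != FRAME_SHAPE:
        raise FrameDimensionError(
            f"thermal frame must be {FRAME_SHAPE[0]}x{FRAME_SHAPE[1]}, "
            f"got {'x'.join(str(s) for s in values.shape)}"
        )
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FrameParseError(
            f"non-finite temperature at row {bad[0]}, column {bad[1]}"
        )
    lo, hi = SENSOR_RANGE
    if values.min() < lo or values.max() > hi:
        raise FrameRangeError(
            f"temperatures outside sensor range [{lo}, {hi}] degC: "
            f"frame spans [{values.min():.2f}, {values.max():.2f}]"
        )


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    counts = {d: first.count(d) for d in ("\t", ";", ",")}
    # A decimal-comma file delimited by ';' or tab also contains many ','.
    # Tabs and semicolons are never decimal marks, so they win when present.
    for d in ("\t", ";"):
        if counts[d] > 0:
            return d
    return ","


def read_thermal_frame(path: str | Path, view_id: str | None = None) -> ThermalFrame:
    """Read one exported raster of temperatures (degC) as a :class:`ThermalFrame`.

    The delimiter is auto-detected among comma, semicolon and tab; a decimal
    comma is accepted when the field delimiter is a semicolon or tab (the
    usual continental-European export convention).

    Parameters
    ----------
    path
        Delimited numeric table, 240 rows x 320 columns.
    view_id
        View label; if omitted it is taken from the JSON sidecar when present,
        else from the file stem.

    Raises
    ------
    FrameDimensionError
        If the table is not 240 x 320 (e.g. a transposed export).
    FrameParseError
        If a cell is not numeric, naming its row and column.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    decimal = "," if delim in (";", "\t") and "," in text else "."
    try:
        df = pd.read_csv(path, sep=delim, decimal=decimal, header=None, dtype=np.float64)
    except ValueError:
        # Re-parse permissively to locate the offending cell.
        df = pd.read_csv(path, sep=delim, decimal=decimal, header=None, dtype=str)
        arr = df.to_numpy()
        for (r, c), cell in np.ndenumerate(arr):
            try:
                float(str(cell).replace(",", ".") if decimal == "," else cell)
            except (TypeError, ValueError):
                raise FrameParseError(
                    f"non-numeric cell {cell!r} at row {r}, column {c} of {path.name}"
                ) from None
        raise
    values = df.to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        bad = np.argwhere(np.isnan(values))[0]
        raise FrameParseError(
            f"empty or non-numeric cell at row {bad[0]}, column {bad[1]} of {path.name}"
        )

    meta = AcquisitionMetadata()
    timestamp = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        timestamp = raw.pop("timestamp", None)
        sidecar_view = raw.pop("view_id", None)
        if view_id is None:
            view_id = sidecar_view
        meta = AcquisitionMetadata(
            **{k: v for k, v in raw.items() if k in AcquisitionMetadata.__dataclass_fields__}
        )
    if view_id is None:
        view_id = path.stem
    return ThermalFrame(values=values, view_id=view_id, timestamp=timestamp, metadata=meta)


def write_thermal_frame(frame: ThermalFrame, path: str | Path) -> None:
    """Write ``frame`` as a comma-delimited table plus a JSON metadata sidecar.

    Round trip contract: ``read_thermal_frame(path)`` reproduces the values to
    within 1e-6 degC and preserves ``view_id`` via the sidecar.
    """
    path = Path(path)
    validate_frame_values(frame.values)
    # %.10g keeps typical skin temperatures (e.g. 36.95) verbatim and bounds
    # the round-trip error well below 1e-6 degC for in-range values.
    np.savetxt(path, frame.values, fmt="%.10g", delimiter=",")
    sidecar = {"view_id": frame.view_id, "timestamp": frame.timestamp}
    sidecar.update(asdict(frame.metadata))
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )


def frame_stats(frame: ThermalFrame) -> dict[str, float]:
    """Min / max / mean of a frame, handy for logs and sanity checks."""
    v = frame.values
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "p99": float(np.percentile(v, 99)),
    }
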