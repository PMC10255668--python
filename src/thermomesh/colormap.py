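"""Temperature <-> RGB codec for false-colour thermal maps.

Temperatures are encoded with a jet colormap whose colour saturation is
anchored to a fixed span (28-37 degC by default): everything at or below the
lower anchor renders as the first colour, everything at or above the upper
anchor as the last.  The jet channels are the closed-form piecewise-linear
ramps

    r(x) = clamp(1.5 - |4x - 3|, 0, 1)
    g(x) = clamp(1.5 - |4x - 2|, 0, 1)
    b(x) = clamp(1.5 - |4x - 1|, 0, 1)

sampled at ``n_levels`` points of x in [0, 1], scaled to 8-bit and rounded
half-up, which reproduces the classic half-intensity blue and red endpoints.

Decoding goes the other way: per-vertex mesh colours produced by texturing
are blends of several projected images, so they generally do not sit on the
colormap arc and cannot be looked up in a table.  A smooth inverse model --
a Gaussian radial-basis interpolator grown centre by centre until its
held-out mean squared error drops below a threshold -- maps any 8-bit RGB
triple back to a temperature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .thermal_io import ThermalFrame


@dataclass(frozen=True)
class ColormapSpec:
    """Anchored jet colormap: temperature span and number of discrete levels."""

    t_low: float = 28.0
    t_high: float = 37.0
    n_levels: int = 256

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError(f"t_low must be < t_high, got [{self.t_low}, {self.t_high}]")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


def jet_channels(x: np.ndarray) -> np.ndarray:
    """Continuous jet colour at normalized position ``x`` in [0, 1].

    Returns float RGB in [0, 1], shape ``x.shape + (3,)``.
    """
    x = np.asarray(x, dtype=np.float64)
    r = np.clip(1.5 - np.abs(4.0 * x - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * x - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * x - 1.0), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def colormap_levels(spec: ColormapSpec) -> tuple[np.ndarray, np.ndarray]:
    """The discrete colormap: level temperatures and their 8-bit colours.

    Returns ``(temperatures, colors)`` with shapes (n_levels,) and
    (n_levels, 3); ``temperatures`` are evenly spaced over the anchor span.
    """
    x = np.linspace(0.0, 1.0, spec.n_levels)
    temps = spec.t_low + x * (spec.t_high - spec.t_low)
    colors = np.floor(jet_channels(x) * 255.0 + 0.5).astype(np.uint8)  # round half-up
    return temps, colors


def encode_temperatures(values: np.ndarray, spec: ColormapSpec | None = None) -> np.ndarray:
    """Map temperatures (degC) to quantized 8-bit jet colours.

    Values are clipped to the anchor span (saturation), normalized, snapped
    to the nearest of ``n_levels`` discrete levels and coloured.
    """
    spec = spec or ColormapSpec()
    values = np.asarray(values, dtype=np.float64)
    x = (np.clip(values, spec.t_low, spec.t_high) - spec.t_low) / (spec.t_high - spec.t_low)
    idx = np.rint(x * (spec.n_levels - 1)).astype(np.intp)
    _, colors = colormap_levels(spec)
    return colors[idx]


def encode_frame(frame: ThermalFrame, spec: ColormapSpec | None = None) -> np.ndarray:
    """Encode one thermal frame as an 8-bit colour image (H, W, 3)."""
    return encode_temperatures(frame.values, spec)


def write_png(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 image as PNG."""
    from PIL import Image

    Image.fromarray(np.ascontiguousarray(image, dtype=np.uint8), mode="RGB").save(str(path))


def read_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path)).convert("RGB"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Colour table (branch of the workflow that inverts the encoding)
# ---------------------------------------------------------------------------

@dataclass
class ColorTable:
    """Deduplicated 1:1 association between temperatures and RGB codes.

    ``temperatures`` is strictly increasing; each row's colour is unique.
    """

    temperatures: np.ndarray  # (n,), degC, strictly increasing
    colors: np.ndarray        # (n, 3), uint8, unique rows

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=np.float64)
        self.colors = np.asarray(self.colors, dtype=np.uint8)
        if len(self.temperatures) != len(self.colors):
            raise ValueError("temperatures and colors must have equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("table temperatures must be strictly increasing")
        if len(np.unique(self.colors.reshape(-1, 3), axis=0)) != len(self.colors):
            raise ValueError("table colours must be unique")

    def __len__(self) -> int:
        return len(self.temperatures)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("temperature,r,g,b\n")
            for t, (r, g, b) in zip(self.temperatures, self.colors):
                fh.write(f"{t:.10g},{r},{g},{b}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["temperature"].to_numpy(), df[["r", "g", "b"]].to_numpy())


#: Temperatures are compared at this resolution (degC) when deciding whether
#: two table entries are duplicates of one another.
DUPLICATE_RESOLUTION = 0.01


def build_color_table(
    frames: list[ThermalFrame] | list[np.ndarray],
    spec: ColormapSpec | None = None,
) -> ColorTable:
    """Tabulate every (temperature, colour) pair occurring in ``frames``.

    Each frame's temperatures are encoded through ``spec``; the resulting
    pairs are pooled over all frames, exact duplicates are dropped, and when
    several distinct temperatures (at 0.01 degC resolution) share one colour
    they are replaced by a single row at their arithmetic mean.  The result
    is sorted by ascending temperature and is independent of frame order.

    Temperatures outside the anchor span are excluded: saturation maps every
    out-of-span value (image background, cold fiducials) onto the two
    extreme colours, so those pairs carry no one-to-one information and
    would drag the extreme rows' averaged temperatures far off the colormap.
    """
    if len(frames) == 0:
        raise ValueError("build_color_table requires at least one frame")
    spec = spec or ColormapSpec()

    all_t = []
    all_c = []
    for fr in frames:
        values = fr.values if isinstance(fr, ThermalFrame) else np.asarray(fr, dtype=np.float64)
        values = values.ravel()
        in_span = (values >= spec.t_low) & (values <= spec.t_high)
        values = values[in_span]
        all_t.append(values)
        all_c.append(encode_temperatures(values, spec).reshape(-1, 3))
    t = np.concatenate(all_t)
    c = np.concatenate(all_c)
    if len(t) == 0:
        raise ValueError("no temperatures within the colormap anchor span")

    # Quantize temperatures to the duplicate-comparison resolution, then keep
    # one copy of each exact (T, rgb) pair.
    tq = np.round(t / DUPLICATE_RESOLUTION) * DUPLICATE_RESOLUTION
    keys = np.column_stack([tq, c.astype(np.float64)])
    uniq = np.unique(keys, axis=0)
    tq_u, c_u = uniq[:, 0], uniq[:, 1:4]

    # Average the distinct temperatures that map to one colour.
    _, inverse = np.unique(c_u, axis=0, return_inverse=True)
    n_colors = inverse.max() + 1
    temp_mean = np.bincount(inverse, weights=tq_u) / np.bincount(inverse)
    color_rows = np.zeros((n_colors, 3))
    color_rows[inverse] = c_u
    order = np.argsort(temp_mean)
    return ColorTable(temp_mean[order], color_rows[order].astype(np.uint8))


def full_ramp_table(spec: ColormapSpec | None = None) -> ColorTable:
    """Colour table of a dense synthetic temperature ramp spanning the anchors.

    Convenience for training an inverse model that covers the whole colormap.
    """
    spec = spec or ColormapSpec()
    temps, _ = colormap_levels(spec)
    ramp = np.tile(np.linspace(spec.t_low, spec.t_high, 320), (240, 1))
    return build_color_table([ramp], spec)


# ---------------------------------------------------------------------------
# Inverse colour model: RGB -> temperature
# ---------------------------------------------------------------------------

class InverseModelError(RuntimeError):
    """The radial-basis model could not reach the target held-out MSE."""


#: Number of samples of the continuous jet curve used for the arc-length
#: coordinate feature (resolution ~0.004 degC over a 9 degC span).
N_ARC_SAMPLES = 2048


def _arc_samples(n: int = N_ARC_SAMPLES) -> tuple[np.ndarray, np.ndarray]:
    u = np.linspace(0.0, 1.0, n)
    return u, jet_channels(u)


def arc_coordinate(rgb01: np.ndarray, n: int = N_ARC_SAMPLES) -> np.ndarray:
    """Arc position in [0, 1] of the jet-curve point nearest to each colour.

    ``rgb01`` has shape (n_points, 3) with channels in [0, 1].  The coordinate
    is a fixed, data-independent reparameterization of colour space: on-arc
    colours map back to their normalized temperature, off-arc blends map to
    the nearest arc point.
    """
    u, arc = _arc_samples(n)
    out = np.empty(len(rgb01))
    for start in range(0, len(rgb01), 4096):
        chunk = rgb01[start : start + 4096]
        d2 = ((chunk[:, None, :] - arc[None, :, :]) ** 2).sum(axis=2)
        out[start : start + 4096] = u[np.argmin(d2, axis=1)]
    return out


@dataclass
class InverseColorModel:
    """Radial-basis model mapping 8-bit RGB triples to temperature (degC).

    The regression basis is the colour's arc-length coordinate along the
    continuous jet curve (which linearizes the target and keeps the fit
    well-posed at the arc ends), a constant, and Gaussian radial basis
    functions over RGB scaled to [0, 1]^3.  The Gaussian centres are grown
    greedily -- the training point with the worst residual is promoted to a
    new centre and all weights refit -- until the mean squared error on a
    held-out half of the colour table drops to ``mse_threshold`` (1e-4
    degC^2 by default) or the centre budget is exhausted.  Output is clipped
    to the colormap anchor span, so blended off-arc colours produced by
    texture smoothing always decode to a finite temperature.
    """

    spec: ColormapSpec = field(default_factory=ColormapSpec)
    mse_threshold: float = 1e-4
    spread: float = 0.35
    max_centers: int = 128
    centers: np.ndarray | None = None   # (m, 3) in [0,1]^3
    weights: np.ndarray | None = None   # (m + 2,): [gaussians..., arc, bias]
    train_mse: float = np.nan
    test_mse: float = np.nan
    split_seed: int | None = None

    @property
    def is_trained(self) -> bool:
        return self.centers is not None and self.weights is not None

    def _design(self, x: np.ndarray) -> np.ndarray:
        phi_cols = []
        if len(self.centers):
            d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
            phi_cols.append(np.exp(-d2 / (self.spread**2)))
        phi_cols.append(arc_coordinate(x)[:, None])
        phi_cols.append(np.ones((len(x), 1)))
        return np.concatenate(phi_cols, axis=1)

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        """Temperatures (degC) for 8-bit RGB triples, shape (..., 3)."""
        if not self.is_trained:
            raise InverseModelError("inverse colour model has not been trained")
        rgb = np.asarray(rgb, dtype=np.float64)
        flat = rgb.reshape(-1, 3) / 255.0
        t = self._design(flat) @ self.weights
        t = np.clip(t, self.spec.t_low, self.spec.t_high)
        return t.reshape(rgb.shape[:-1])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "t_low": self.spec.t_low,
            "t_high": self.spec.t_high,
            "n_levels": self.spec.n_levels,
            "mse_threshold": self.mse_threshold,
            "spread": self.spread,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "train_mse": self.train_mse,
            "test_mse": self.test_mse,
            "split_seed": self.split_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "InverseColorModel":
        raw = json.loads(Path(path).read_text())
        model = cls(
            spec=ColormapSpec(raw["t_low"], raw["t_high"], raw["n_levels"]),
            mse_threshold=raw["mse_threshold"],
            spread=raw["spread"],
        )
        model.centers = np.asarray(raw["centers"], dtype=np.float64)
        model.weights = np.asarray(raw["weights"], dtype=np.float64)
        model.train_mse = raw["train_mse"]
        model.test_mse = raw["test_mse"]
        model.split_seed = raw["split_seed"]
        return model


def train_inverse_model(
    table: ColorTable,
    split_seed: int = 0,
    mse_threshold: float = 1e-4,
    spread: float = 0.35,
    max_centers: int = 128,
    spec: ColormapSpec | None = None,
) -> InverseColorModel:
    """Fit the RGB -> temperature model on a random half of ``table``.

    The table rows are split 50/50 at random (``split_seed``); Gaussian
    centres are added greedily on the worst training residual until the mean
    squared error on the held-out half reaches ``mse_threshold``.

    Raises
    ------
    InverseModelError
        If the centre budget is exhausted first (reports the best MSE seen).
    """
    if len(table) < 4:
        raise ValueError(f"colour table must have >= 4 rows, got {len(table)}")
    spec = spec or ColormapSpec()

    rng = np.random.default_rng(split_seed)
    n = len(table)
    perm = rng.permutation(n)
    half = n // 2
    train_idx, test_idx = np.sort(perm[:half]), np.sort(perm[half:])

    x = table.colors.astype(np.float64) / 255.0
    y = table.temperatures
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_te, y_te = x[test_idx], y[test_idx]

    model = InverseColorModel(
        spec=spec, mse_threshold=mse_threshold, spread=spread,
        max_centers=max_centers, split_seed=split_seed,
    )

    # Start from the constant (bias-only) fit, then grow.
    centers = np.empty((0, 3))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(min(max_centers, len(x_tr)) + 1):
        model.centers = centers
        phi = model._design(x_tr)
        # Ridge-regularized LSQ keeps nearby centres from blowing up weights.
        lam = 1e-10
        a = phi.T @ phi + lam * np.eye(phi.shape[1])
        w = np.linalg.solve(a, phi.T @ y_tr)
        model.weights = w
        resid = phi @ w - y_tr
        train_mse = float(np.mean(resid**2))
        test_mse = float(np.mean((model._design(x_te) @ w - y_te) ** 2))
        if best is None or test_mse < best[0]:
            best = (test_mse, centers.copy(), w.copy())
        if test_mse <= mse_threshold:
            model.train_mse = train_mse
            model.test_mse = test_mse
            return model
        # Promote the worst-fit training point not already a centre.
        order = np.argsort(-np.abs(resid))
        for i in order:
            cand = x_tr[i]
            if len(centers) == 0 or np.min(((centers - cand) ** 2).sum(axis=1)) > 1e-12:
                centers = np.vstack([centers, cand])
                break
        else:
            break  # every training point is already a centre

    raise InverseModelError(
        f"centre budget ({max_centers}) exhausted; best held-out MSE "
        f"{best[0]:.3e} > threshold {mse_threshold:.0e}"
    )


def rgb_to_temperature(model: InverseColorModel, rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB triples to temperatures (degC) via the trained model."""
    return model.predict(rgb)
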