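"""Haemodynamic metrics on time-resolved vector fields.

Operates on :class:`VectorFieldSeries`: velocity or wall-shear-stress
(WSS) samples on a fixed point set with per-point quadrature measures
(areas for surfaces, volumes for grids). Gradient-based metrics
(vorticity, viscous dissipation) additionally require structured-grid
metadata and use second-order central differences.

Metric definitions:

* TAWSS — time average of the WSS *magnitude* over the cycle,
  ``(1/T) \\int |tau| dt``;
* OSI — ``0.5 (1 - |\\int tau dt| / \\int |tau| dt)``, zero for
  unidirectional shear, 0.5 for perfect reversal;
* vorticity — ``|curl u|``;
* TKE — ``k = 0.5 <|u'|^2>`` over an ensemble of realizations;
* viscous energy loss — ``\\int_t \\int_V (mu/2) sum_ij (du_i/dx_j +
  du_j/dx_i)^2 dV dt`` (joules), the strain-rate dissipation integrated
  over the sampled volume and time window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from graftflow.constants import PhysicalConstants

__all__ = [
    "VectorFieldSeries",
    "MetricMap",
    "tawss",
    "osi",
    "vorticity",
    "tke",
    "viscous_energy_loss",
    "section_flow_rate",
    "reverse_flow",
    "reynolds_number",
    "write_field_series",
    "read_field_series",
]

logger = logging.getLogger(__name__)


@dataclass
class VectorFieldSeries:
    """Time-resolved vector samples on a fixed point set.

    Attributes
    ----------
    times : (T,) ndarray
        Uniform, strictly increasing sample times, s.
    points : (N, 3) ndarray
        Sample positions, m.
    vectors : (T, N, 3) ndarray
        Velocity (m/s) or WSS (Pa) vectors.
    measure : (N,) ndarray
        Quadrature weight per point: area (m^2) for surfaces, volume
        (m^3) for grids. Zero marks points outside the flow domain.
    kind : {"velocity", "wall_shear"}
    grid_shape, spacing : optional structured-grid metadata; required by
        gradient-based metrics. Points must then be the row-major
        flattening of the grid.
    """

    times: np.ndarray
    points: np.ndarray
    vectors: np.ndarray
    measure: np.ndarray
    kind: str
    grid_shape: tuple[int, int, int] | None = None
    spacing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.measure = np.asarray(self.measure, dtype=float)
        t, n = self.times.size, self.points.shape[0]
        if self.vectors.shape != (t, n, 3):
            raise ValueError(f"vectors must have shape {(t, n, 3)}, got {self.vectors.shape}")
        if self.measure.shape != (n,):
            raise ValueError("measure must be per-point")
        if np.any(self.measure < 0):
            raise ValueError("measure must be non-negative")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8)):
            raise ValueError("times must be strictly increasing and uniform")
        if self.kind not in ("velocity", "wall_shear"):
            raise ValueError("kind must be 'velocity' or 'wall_shear'")
        if self.spacing is not None:
            self.spacing = np.asarray(self.spacing, dtype=float)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def _require_grid(self, op: str) -> None:
        if self.grid_shape is None or self.spacing is None:
            raise ValueError(
                f"{op} requires a structured grid; build the field with the "
                "synthetic_fields generators or attach grid_shape/spacing"
            )


@dataclass
class MetricMap:
    """A per-point scalar metric."""

    points: np.ndarray
    values: np.ndarray
    name: str
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.points.shape[0]:
            raise ValueError("values must be per-point")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"metric {self.name!r} produced non-finite values")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                self.name: self.values,
            }
        ).to_csv(path, index=False)


def tawss(wss: VectorFieldSeries) -> MetricMap:
    """Time-averaged WSS magnitude over the sampled cycle, Pa."""
    if wss.kind != "wall_shear":
        raise ValueError("tawss expects a wall_shear field")
    if wss.times.size < 2:
        raise ValueError("tawss needs at least two time samples")
    mag = np.linalg.norm(wss.vectors, axis=2)  # (T, N)
    avg = np.trapezoid(mag, wss.times, axis=0) / wss.duration
    return MetricMap(points=wss.points, values=avg, name="tawss", units="Pa")


def osi(wss: VectorFieldSeries) -> MetricMap:
    """Oscillatory shear index, dimensionless in [0, 0.5].

    Points where the cumulative WSS magnitude vanishes are reported as 0
    and counted in the log.
    """
    if wss.kind != "wall_shear":
        raise ValueError("osi expects a wall_shear field")
    vec_int = np.trapezoid(wss.vectors, wss.times, axis=0)  # (N, 3)
    mag_int = np.trapezoid(np.linalg.norm(wss.vectors, axis=2), wss.times, axis=0)
    degenerate = mag_int == 0.0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("osi: %d degenerate points (zero cumulative WSS) set to 0", n_deg)
    safe = np.where(degenerate, 1.0, mag_int)
    values = 0.5 * (1.0 - np.linalg.norm(vec_int, axis=1) / safe)
    values = np.where(degenerate, 0.0, np.clip(values, 0.0, 0.5))
    return MetricMap(points=wss.points, values=values, name="osi", units="-")


def _gradients(field: np.ndarray, shape, spacing) -> np.ndarray:
    """du_i/dx_j on the grid: returns array (..., nx, ny, nz, 3comp, 3dir)."""
    grid = field.reshape(*field.shape[:-2], *shape, 3)
    grads = np.stack(
        [
            np.stack(
                np.gradient(grid[..., c], *spacing, axis=(-3, -2, -1)), axis=-1
            )
            for c in range(3)
        ],
        axis=-2,
    )
    return grads  # (..., nx, ny, nz, i, j)


def vorticity(vel: VectorFieldSeries, time_average: bool = True):
    """Vorticity magnitude |curl u| (s^-1) on a structured grid.

    Returns a :class:`MetricMap` of the time-averaged magnitude, or the
    per-time ``(T, N)`` array when ``time_average=False``.
    """
    if vel.kind != "velocity":
        raise ValueError("vorticity expects a velocity field")
    vel._require_grid("vorticity")
    g = _gradients(vel.vectors, vel.grid_shape, vel.spacing)  # (T,nx,ny,nz,i,j)
    wx = g[..., 2, 1] - g[..., 1, 2]
    wy = g[..., 0, 2] - g[..., 2, 0]
    wz = g[..., 1, 0] - g[..., 0, 1]
    mag = np.sqrt(wx**2 + wy**2 + wz**2).reshape(vel.times.size, -1)
    if not time_average:
        return mag
    if vel.times.size > 1:
        avg = np.trapezoid(mag, vel.times, axis=0) / vel.duration
    else:
        avg = mag[0]
    return MetricMap(points=vel.points, values=avg, name="vorticity", units="1/s")


def tke(mean_vel: VectorFieldSeries, realizations: list[VectorFieldSeries]) -> MetricMap:
    """Turbulent kinetic energy k = 0.5 <|u'|^2> per point, m^2/s^2.

    Fluctuations are measured against the supplied ensemble mean and
    averaged over realizations and time samples.
    """
    if not realizations:
        raise ValueError("at least one realization is required")
    for r in realizations:
        if r.vectors.shape != mean_vel.vectors.shape or not np.allclose(
            r.points, mean_vel.points
        ):
            raise ValueError("realizations must share the grid of the mean field")
    sq = np.zeros(mean_vel.points.shape[0])
    for r in realizations:
        fluct = r.vectors - mean_vel.vectors  # (T, N, 3)
        sq += np.mean(np.sum(fluct**2, axis=2), axis=0)
    values = 0.5 * sq / len(realizations)
    return MetricMap(points=mean_vel.points, values=values, name="tke", units="m^2/s^2")


def viscous_energy_loss(
    vel: VectorFieldSeries,
    constants: PhysicalConstants,
    t1: float,
    t2: float,
) -> float:
    """Viscous dissipation integrated over volume and [t1, t2], joules.

    ``\\int_t \\int_V (mu/2) sum_ij (du_i/dx_j + du_j/dx_i)^2 dV dt``
    with gradients by central differences. For a steady field sampled at
    two instants this equals dissipation-rate x window length.
    """
    if vel.kind != "velocity":
        raise ValueError("viscous_energy_loss expects a velocity field")
    vel._require_grid("viscous_energy_loss")
    if not (vel.times[0] <= t1 < t2 <= vel.times[-1]):
        raise ValueError(
            f"[t1, t2] = [{t1}, {t2}] outside the sampled window "
            f"[{vel.times[0]}, {vel.times[-1]}]"
        )
    mask = (vel.times >= t1 - 1e-12) & (vel.times <= t2 + 1e-12)
    times = vel.times[mask]
    g = _gradients(vel.vectors[mask], vel.grid_shape, vel.spacing)
    sym = g + np.swapaxes(g, -1, -2)  # du_i/dx_j + du_j/dx_i
    density = constants.mu / 2.0 * np.sum(sym**2, axis=(-1, -2))  # (Tm,nx,ny,nz)
    rate = density.reshape(times.size, -1) @ vel.measure  # W per time
    return float(np.trapezoid(rate, times))


def _slice_indices(vel: VectorFieldSeries, plane_point, plane_normal):
    """Nearest axis-aligned grid slice to the requested plane."""
    vel._require_grid("section operations")
    normal = np.asarray(plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    axis = int(np.argmax(np.abs(normal)))
    if abs(abs(normal[axis]) - 1.0) > 1e-9:
        raise ValueError("section planes must be aligned with a grid axis")
    shape = vel.grid_shape
    coords = vel.points[:, axis].reshape(shape)
    axis_coords = np.moveaxis(coords, axis, 0)[(slice(None),) + (0,) * 2]
    target = float(np.asarray(plane_point, dtype=float)[axis])
    if target < axis_coords.min() - 1e-12 or target > axis_coords.max() + 1e-12:
        raise ValueError("plane does not intersect the sampled domain")
    k = int(np.argmin(np.abs(axis_coords - target)))
    idx = np.arange(np.prod(shape)).reshape(shape)
    flat = np.moveaxis(idx, axis, 0)[k].ravel()
    sign = float(np.sign(normal[axis]))
    area = vel.measure[flat] / vel.spacing[axis]
    return flat, axis, sign, area


def section_flow_rate(vel: VectorFieldSeries, plane_point, plane_normal) -> np.ndarray:
    """Volumetric flow through an axis-aligned section, m^3/s per time."""
    if vel.kind != "velocity":
        raise ValueError("section_flow_rate expects a velocity field")
    flat, axis, sign, area = _slice_indices(vel, plane_point, plane_normal)
    un = sign * vel.vectors[:, flat, axis]  # (T, n_slice)
    return un @ area


def reverse_flow(vel: VectorFieldSeries, plane_point, plane_normal) -> dict:
    """Reverse-flow indices through a section.

    The plane normal points toward the aortic root; flow with
    ``u . n < 0`` is *reverse* (root-directed against the reference
    direction convention of the caller). Returns per-time arrays of the
    reverse area fraction, area-weighted mean and peak reverse speed,
    plus cycle aggregates.
    """
    if vel.kind != "velocity":
        raise ValueError("reverse_flow expects a velocity field")
    flat, axis, sign, area = _slice_indices(vel, plane_point, plane_normal)
    total_area = float(area.sum())
    if total_area == 0:
        raise ValueError("section has zero flow area")
    un = sign * vel.vectors[:, flat, axis]  # (T, n_slice)
    neg = np.minimum(un, 0.0)
    rev_area = (un < 0) @ area
    fraction = rev_area / total_area
    mean_rev = np.where(rev_area > 0, (-neg) @ area / np.maximum(rev_area, 1e-300), 0.0)
    peak_rev = (-neg).max(axis=1)
    return {
        "reverse_fraction": fraction,
        "mean_reverse_velocity": mean_rev,
        "peak_reverse_velocity": peak_rev,
        "cycle_mean_fraction": float(fraction.mean()),
        "cycle_mean_reverse_velocity": float(mean_rev.mean()),
        "cycle_peak_reverse_velocity": float(peak_rev.max()),
    }


def reynolds_number(
    constants: PhysicalConstants, mean_speed: float, diameter: float
) -> float:
    """Tube Reynolds number rho U D / mu."""
    if mean_speed < 0 or diameter <= 0:
        raise ValueError("mean_speed must be >= 0 and diameter > 0")
    return constants.rho * mean_speed * diameter / constants.mu


# -- columnar container IO ---------------------------------------------------


def write_field_series(field_series: VectorFieldSeries, out_dir: str | Path) -> Path:
    """Write a field series as one CSV per time step plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    steps = []
    for i, t in enumerate(field_series.times):
        name = f"step_{i:04d}.csv"
        pd.DataFrame(
            {
                "x": field_series.points[:, 0],
                "y": field_series.points[:, 1],
                "z": field_series.points[:, 2],
                "vx": field_series.vectors[i, :, 0],
                "vy": field_series.vectors[i, :, 1],
                "vz": field_series.vectors[i, :, 2],
                "measure": field_series.measure,
            }
        ).to_csv(out / name, index=False)
        steps.append({"t": float(t), "file": name})
    manifest = {
        "kind": field_series.kind,
        "steps": steps,
        "grid_shape": list(field_series.grid_shape) if field_series.grid_shape else None,
        "spacing": field_series.spacing.tolist() if field_series.spacing is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def read_field_series(manifest_path: str | Path) -> VectorFieldSeries:
    """Read a field series written by :func:`write_field_series`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    times, vectors = [], []
    points = measure = None
    for step in manifest["steps"]:
        df = pd.read_csv(manifest_path.parent / step["file"])
        if points is None:
            points = df[["x", "y", "z"]].to_numpy()
            measure = df["measure"].to_numpy()
        times.append(step["t"])
        vectors.append(df[["vx", "vy", "vz"]].to_numpy())
    return VectorFieldSeries(
        times=np.array(times),
        points=points,
        vectors=np.array(vectors),
        measure=measure,
        kind=manifest["kind"],
        grid_shape=tuple(manifest["grid_shape"]) if manifest.get("grid_shape") else None,
        spacing=np.array(manifest["spacing"]) if manifest.get("spacing") else None,
    )
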