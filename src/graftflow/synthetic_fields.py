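"""Seeded analytic flow fixtures with closed-form expectations.

Every generator returns a :class:`~graftflow.field_metrics.VectorFieldSeries`
together with an *analytic record*: the closed-form quantities (flow
rate, wall shear, curl, dissipation, OSI, ...) the field is constructed
to exhibit. Metric implementations are validated only against these
records, never against numbers measured from the implementation itself.

Fixtures:

* Poiseuille flow in a circular tube — parabolic axial profile with
  known Hagen-Poiseuille flow rate, wall shear and dissipation;
* solid-body rotation — uniform curl ``2 Omega``, zero strain;
* oscillating wall shear — a direction-switching WSS program whose OSI
  is a closed-form function of the reversal fraction;
* uniform flow — zero vorticity, zero dissipation;
* noisy Fourier waveform samples for fit-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

from graftflow.field_metrics import VectorFieldSeries
from graftflow.waveforms import FourierSeries, WaveformSamples, eval_fourier

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_poiseuille",
    "make_solid_rotation",
    "make_oscillating_wss",
    "make_uniform_flow",
    "make_noisy_waveform",
]


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    kind: str  # poiseuille | solid_rotation | oscillating_wss | uniform | noisy_waveform
    params: dict[str, Any] = dc_field(default_factory=dict)
    grid: tuple[int, int, int] | None = None
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    makers = {
        "poiseuille": make_poiseuille,
        "solid_rotation": make_solid_rotation,
        "oscillating_wss": make_oscillating_wss,
        "uniform": make_uniform_flow,
    }
    if spec.kind == "noisy_waveform":
        return make_noisy_waveform(seed=spec.seed, **spec.params)
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    kwargs = dict(spec.params)
    if spec.grid is not None:
        kwargs["n"] = spec.grid[0]
    return makers[spec.kind](**kwargs)


def _circle_fractions(x: np.ndarray, y: np.ndarray, radius: float, h: float,
                      subsample: int) -> np.ndarray:
    """In-lumen area fraction of each (x, y) cell, by subsampling."""
    offs = (np.arange(subsample) + 0.5) / subsample - 0.5
    sx = x[:, None, None, None] + offs[None, None, :, None] * h
    sy = y[None, :, None, None] + offs[None, None, None, :] * h
    inside = (sx**2 + sy**2) <= radius**2
    return inside.mean(axis=(2, 3))


def make_poiseuille(
    radius: float = 0.01,
    length: float = 0.1,
    dp: float = 100.0,
    mu: float = 0.004,
    n: int = 48,
    nz: int = 8,
    n_times: int = 2,
    subsample: int = 8,
) -> tuple[VectorFieldSeries, dict]:
    """Steady Poiseuille flow in a circular tube along +z.

    The parabolic profile ``u_z = dp (R^2 - r^2) / (4 mu L)`` is sampled
    on an ``n x n x nz`` Cartesian grid spanning the lumen (the smooth
    analytic extension is kept outside the lumen so central differences
    stay exact; the quadrature measure is zero there). The analytic
    record carries the Hagen-Poiseuille flow rate, wall shear,
    dissipation rate, and velocity scales.
    """
    if min(radius, length, mu) <= 0:
        raise ValueError("radius, length and mu must be strictly positive")
    if n < 8 or nz < 2:
        raise ValueError("grid too coarse: need n >= 8 and nz >= 2")
    h = 2.0 * radius / n
    hz = length / nz
    x = -radius + (np.arange(n) + 0.5) * h
    z = (np.arange(nz) + 0.5) * hz
    xx, yy, zz = np.meshgrid(x, x, z, indexing="ij")
    points = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    r2 = xx**2 + yy**2
    uz = dp * (radius**2 - r2) / (4.0 * mu * length)
    vec = np.zeros((n, n, nz, 3))
    vec[..., 2] = uz
    frac = _circle_fractions(x, x, radius, h, subsample)
    measure = (frac[:, :, None] * np.ones(nz)[None, None, :] * h * h * hz).ravel()
    times = np.linspace(0.0, 1.0, n_times)
    vectors = np.broadcast_to(vec.reshape(-1, 3), (n_times, n * n * nz, 3)).copy()
    fieldseries = VectorFieldSeries(
        times=times,
        points=points,
        vectors=vectors,
        measure=measure,
        kind="velocity",
        grid_shape=(n, n, nz),
        spacing=np.array([h, h, hz]),
    )
    q = np.pi * radius**4 * dp / (8.0 * mu * length)
    analytic = {
        "flow_rate": q,
        "wall_shear": dp * radius / (2.0 * length),
        "dissipation_rate": dp * q,
        "max_velocity": dp * radius**2 / (4.0 * mu * length),
        "mean_velocity": q / (np.pi * radius**2),
        "radius": radius,
        "length": length,
        "dp": dp,
        "mu": mu,
    }
    return fieldseries, analytic


def make_solid_rotation(
    omega=(0.0, 0.0, 5.0),
    n: int = 24,
    extent: float = 0.05,
    n_times: int = 2,
    uniform_velocity=(0.0, 0.0, 0.0),
) -> tuple[VectorFieldSeries, dict]:
    """Rigid-body rotation ``u = Omega x r`` (plus an optional uniform flow).

    Curl magnitude is ``2 |Omega|`` everywhere and the strain rate — and
    with it the viscous dissipation — is identically zero.
    """
    omega = np.asarray(omega, dtype=float)
    u0 = np.asarray(uniform_velocity, dtype=float)
    h = extent / n
    c = -extent / 2 + (np.arange(n) + 0.5) * h
    xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
    points = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    vec = np.cross(np.broadcast_to(omega, points.shape), points) + u0
    times = np.linspace(0.0, 1.0, n_times)
    vectors = np.broadcast_to(vec, (n_times, *vec.shape)).copy()
    fieldseries = VectorFieldSeries(
        times=times,
        points=points,
        vectors=vectors,
        measure=np.full(points.shape[0], h**3),
        kind="velocity",
        grid_shape=(n, n, n),
        spacing=np.array([h, h, h]),
    )
    analytic = {"curl_magnitude": 2.0 * float(np.linalg.norm(omega)),
                "dissipation_rate": 0.0}
    return fieldseries, analytic


def make_oscillating_wss(
    amplitude: float = 2.0,
    reversal_fraction: float = 0.5,
    period: float = 1.0,
    n_points: int = 16,
    n_times: int = 64,
    direction=(1.0, 0.0, 0.0),
) -> tuple[VectorFieldSeries, dict]:
    """Direction-switching WSS program with a tunable reversal fraction.

    The shear points along ``+direction`` for the first ``1 - f`` of the
    cycle and along ``-direction`` for the final ``f`` (zero exactly at
    the switch instant, so trapezoidal integrals of symmetric programs
    cancel exactly). Closed-form OSI: ``0.5 (1 - |1 - 2 f|)`` — 0 with no
    reversal, 0.5 for the symmetric half-cycle reversal.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if not 0.0 <= reversal_fraction <= 1.0:
        raise ValueError("reversal_fraction must lie in [0, 1]")
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    times = np.linspace(0.0, period, n_times + 1)
    if reversal_fraction == 0.0:
        sgn = np.ones(times.size)
    elif reversal_fraction == 1.0:
        sgn = -np.ones(times.size)
    else:
        t_switch = (1.0 - reversal_fraction) * period
        sgn = np.where(times < t_switch - 1e-12, 1.0,
                       np.where(times > t_switch + 1e-12, -1.0, 0.0))
    points = np.column_stack(
        [np.linspace(0, 1, n_points), np.zeros(n_points), np.zeros(n_points)]
    )
    vectors = amplitude * sgn[:, None, None] * d[None, None, :]
    vectors = np.broadcast_to(vectors, (times.size, n_points, 3)).copy()
    fieldseries = VectorFieldSeries(
        times=times,
        points=points,
        vectors=vectors,
        measure=np.ones(n_points),
        kind="wall_shear",
    )
    analytic = {
        "osi": 0.5 * (1.0 - abs(1.0 - 2.0 * reversal_fraction)),
        "tawss": amplitude,
    }
    return fieldseries, analytic


def make_uniform_flow(
    velocity=(1.0, 0.0, 0.0), n: int = 16, extent: float = 0.05, n_times: int = 2
) -> tuple[VectorFieldSeries, dict]:
    """Spatially uniform flow: zero vorticity, zero dissipation."""
    fieldseries, _ = make_solid_rotation(
        omega=(0.0, 0.0, 0.0), n=n, extent=extent, n_times=n_times,
        uniform_velocity=velocity,
    )
    analytic = {"curl_magnitude": 0.0, "dissipation_rate": 0.0,
                "speed": float(np.linalg.norm(velocity))}
    return fieldseries, analytic


def make_noisy_waveform(
    series: FourierSeries,
    sigma: float,
    n: int,
    seed: int = 0,
    period: float | None = None,
) -> WaveformSamples:
    """Uniform samples of a Fourier series with additive Gaussian noise.

    Reproducible for a fixed seed; ``n`` must support an 8-harmonic fit
    (``n >= 2 * n_terms + 1``).
    """
    if n < 2 * series.n_terms + 1:
        raise ValueError(f"need at least {2 * series.n_terms + 1} samples")
    period = period if period is not None else series.period
    rng = np.random.default_rng(seed)
    t = (np.arange(n) + 0.5) * period / n
    value = eval_fourier(series, t) + rng.normal(0.0, sigma, size=n)
    return WaveformSamples(t=t, value=value, period=period)
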