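"""Inlet boundary waveforms for the LVAD-supported aorta.

Two flows enter the aorta under HeartMate III (HMIII) support: the pump's
outflow-graft (OG) flow, modulated by the controller's *artificial pulse*
(a programmed speed excursion repeating every 2 s), and a small residual
native cardiac ejection through the aortic valve (AV), present only when
the valve opens — assumed here once every several pump cycles.

Both waveforms are represented as truncated Fourier series

    V(t) = a0 + sum_{n=1}^{N} a_n cos(n w t) + sum_{n=1}^{N} b_n sin(n w t)

with N = 8 terms by default. Fitting uses ordinary least squares on the
sine/cosine design matrix so that non-uniform sampling is supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FourierSeries",
    "PulseSchedule",
    "WaveformSamples",
    "InletProgram",
    "eval_fourier",
    "fit_fourier",
    "hm3_speed",
    "og_flow_waveform",
    "native_hf_waveform",
    "combined_inlet",
]


@dataclass
class FourierSeries:
    """Truncated Fourier series of a periodic waveform.

    Attributes
    ----------
    a0 : float
        Constant (offset) term, the cycle mean, in waveform units.
    a, b : ndarray
        Cosine and sine coefficients for harmonics 1..n_terms.
    omega : float
        Fundamental angular frequency, rad/s. Period is ``2*pi/omega``.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    omega: float

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1D arrays of equal length")
        if not self.omega > 0:
            raise ValueError("omega must be strictly positive")

    @property
    def n_terms(self) -> int:
        return self.a.size

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    def __call__(self, t):
        return eval_fourier(self, t)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "a0": self.a0,
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "omega": self.omega,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FourierSeries":
        d = json.loads(Path(path).read_text())
        return cls(a0=d["a0"], a=np.array(d["a"]), b=np.array(d["b"]), omega=d["omega"])


@dataclass
class PulseSchedule:
    """The HMIII artificial-pulse speed program.

    Every cycle the controller drops the set speed by ``drop_rpm`` for
    ``drop_dur`` seconds, raises it by ``rise_rpm`` *from the reduced
    speed* for ``rise_dur`` seconds, then returns to the set speed for
    ``rest_dur`` seconds. Defaults give the published 2 s cycle.

    ``rise_from_base=True`` selects the alternative reading in which the
    rise is measured from the set speed instead of the reduced speed.
    """

    base_rpm: float = 5500.0
    drop_rpm: float = 2000.0
    drop_dur: float = 0.15
    rise_rpm: float = 4000.0
    rise_dur: float = 0.2
    rest_dur: float = 1.65
    rise_from_base: bool = False
    speed_band: tuple[float, float] = (5000.0, 6000.0)

    def __post_init__(self) -> None:
        if min(self.drop_dur, self.rise_dur, self.rest_dur) < 0:
            raise ValueError("phase durations must be non-negative")
        lo, hi = self.speed_band
        if not lo <= self.base_rpm <= hi:
            raise ValueError(
                f"base_rpm={self.base_rpm} outside the validity band [{lo}, {hi}] rpm"
            )

    @property
    def period(self) -> float:
        return self.drop_dur + self.rise_dur + self.rest_dur


@dataclass
class WaveformSamples:
    """Sampled waveform over one period: times (s) and values."""

    t: np.ndarray
    value: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape or self.t.ndim != 1:
            raise ValueError("t and value must be 1D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.t.size and (self.t[0] < 0 or self.t[-1] > self.period):
            raise ValueError("sample times must lie within [0, period]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_seconds": self.t, "value": self.value}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, period: float | None = None) -> "WaveformSamples":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        v = df.iloc[:, 1].to_numpy(float)
        return cls(t=t, value=v, period=period if period is not None else float(t[-1]))


@dataclass
class InletProgram:
    """The combined two-inlet boundary program.

    The OG flow runs continuously with period ``og_period``; the native
    (AV) flow is a ``residual_fraction``-scaled copy of the heart-failure
    ejection waveform, active during exactly one native cycle at the start
    of every block of ``opening_interval`` pump cycles. ``av_open=False``
    models the persistently closed valve.
    """

    og: FourierSeries
    native: FourierSeries
    residual_fraction: float = 0.05
    opening_interval: int = 5
    og_period: float = 2.0
    av_open: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")
        if self.opening_interval < 1:
            raise ValueError("opening_interval must be >= 1")


def eval_fourier(series: FourierSeries, t):
    """Evaluate a truncated Fourier series at times ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    n = np.arange(1, series.n_terms + 1)
    phase = np.multiply.outer(t, n) * series.omega  # (..., n_terms)
    out = series.a0 + np.cos(phase) @ series.a + np.sin(phase) @ series.b
    return out if out.shape else float(out)


def fit_fourier(samples: WaveformSamples, n_terms: int = 8) -> FourierSeries:
    """Least-squares Fourier fit of sampled data over one period.

    Solves for the 2*n_terms+1 coefficients that minimise the sum of
    squared residuals on the given samples. Requires at least
    ``2*n_terms+1`` samples.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    m = samples.t.size
    if m < 2 * n_terms + 1:
        raise ValueError(
            f"need at least {2 * n_terms + 1} samples to fit {n_terms} harmonics, got {m}"
        )
    omega = 2.0 * np.pi / samples.period
    n = np.arange(1, n_terms + 1)
    phase = np.multiply.outer(samples.t, n) * omega
    design = np.hstack([np.ones((m, 1)), np.cos(phase), np.sin(phase)])
    coef, *_ = np.linalg.lstsq(design, samples.value, rcond=None)
    return FourierSeries(
        a0=float(coef[0]), a=coef[1 : n_terms + 1], b=coef[n_terms + 1 :], omega=omega
    )


def hm3_speed(t, schedule: PulseSchedule):
    """Instantaneous pump speed (rpm) under the artificial-pulse program.

    Piecewise constant and periodic: reduced speed during the drop phase,
    elevated speed during the rise phase, set speed for the rest of the
    cycle.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = np.mod(t, schedule.period)
    low = schedule.base_rpm - schedule.drop_rpm
    high = (schedule.base_rpm if schedule.rise_from_base else low) + schedule.rise_rpm
    out = np.full(tau.shape, schedule.base_rpm)
    out[tau < schedule.drop_dur + schedule.rise_dur] = high
    out[tau < schedule.drop_dur] = low
    return out if out.shape else float(out)


def og_flow_waveform(
    schedule: PulseSchedule, mean_flow: float, n_terms: int = 8, n_samples: int = 256
) -> FourierSeries:
    """OG volumetric-flow waveform implied by the artificial-pulse program.

    The pump speed schedule is mapped to flow by a proportional
    speed-to-flow calibration scaled so the cycle mean equals
    ``mean_flow`` (m^3/s), then fitted with an ``n_terms`` Fourier series.
    The shape and the mean are what the downstream network consumes; the
    absolute speed-to-flow gain of the pump is not modelled.
    """
    if mean_flow <= 0:
        raise ValueError("mean_flow must be strictly positive")
    # Uniform midpoint sampling: the sample mean then equals the exact
    # cycle mean of the piecewise-constant speed up to phase-boundary
    # rounding of order period/n_samples.
    t = (np.arange(n_samples) + 0.5) * schedule.period / n_samples
    speed = hm3_speed(t, schedule)
    q = mean_flow * speed / speed.mean()
    series = fit_fourier(
        WaveformSamples(t=t, value=q, period=schedule.period), n_terms=n_terms
    )
    return series


def native_hf_waveform(
    cardiac_output: float,
    period: float = 0.7,
    systolic_fraction: float = 0.35,
    n_terms: int = 8,
    n_samples: int = 256,
) -> FourierSeries:
    """Residual native cardiac ejection waveform in chronic heart failure.

    A half-sine ejection template — zero through diastole, a non-negative
    half-sine lobe over the systolic fraction of the cycle — is scaled so
    the cycle-mean flow equals ``cardiac_output`` (m^3/s), then fitted
    with an ``n_terms`` Fourier series.
    """
    if cardiac_output < 0:
        raise ValueError("cardiac_output must be non-negative")
    if not 0.0 < systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie strictly in (0, 1)")
    if period <= 0:
        raise ValueError("period must be positive")
    t = (np.arange(n_samples) + 0.5) * period / n_samples
    ts = systolic_fraction * period
    # half-sine lobe: mean over the cycle = peak * (2/pi) * systolic_fraction
    peak = cardiac_output * np.pi / (2.0 * systolic_fraction)
    q = np.where(t < ts, peak * np.sin(np.pi * t / ts), 0.0)
    return fit_fourier(WaveformSamples(t=t, value=q, period=period), n_terms=n_terms)


def combined_inlet(program: InletProgram, t):
    """Evaluate both inlets at times ``t``.

    Returns ``(og_flow, av_flow)`` in m^3/s. The OG component is always
    active. The AV component is the residual-scaled native waveform during
    one native cycle at the start of each block of ``opening_interval``
    pump cycles, and zero otherwise.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    og_q = eval_fourier(program.og, t)
    block = program.opening_interval * program.og_period
    t_local = np.mod(t, block)
    native_period = program.native.period
    open_window = t_local < native_period
    av_q = np.zeros(t.shape)
    if program.av_open and program.residual_fraction > 0:
        av_q = np.where(
            open_window,
            program.residual_fraction * eval_fourier(program.native, t_local),
            0.0,
        )
    if t.shape:
        return og_q, av_q
    return float(og_q), float(av_q)
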