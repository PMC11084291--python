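"""Three-element (RCR) Windkessel outlet models.

Each aortic branch is drained through a proximal resistance ``Rp`` in
series with a parallel pair of distal resistance ``Rd`` and compliance
``C``. The capacitor pressure ``Pc`` obeys

    dPc/dt = Q/C - Pc/(Rd*C)

and the branch inlet pressure is ``P = Pc + Q*Rp``.

The seven-outlet parameter set shipped with the package (see
:func:`table3_branches`) corresponds to an LVAD-supported systemic state:
mean arterial pressure 73 mmHg at a cardiac output of 6.7e-5 m^3/s, with
roughly 7% of each branch's resistance placed proximally.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from graftflow.constants import MMHG_TO_PA

__all__ = [
    "WK3Params",
    "SystemicState",
    "BranchSpec",
    "wk3_response",
    "estimate_rcr",
    "total_parallel_resistance",
    "table3_branches",
    "table3_flow_fractions",
]

#: Sum of the shipped seven-branch compliances, m^3/Pa.
DEFAULT_TOTAL_COMPLIANCE = 1.1169e-8

#: Proximal share of each branch's total resistance (inverting the shipped
#: table gives ~7.0% for every row).
DEFAULT_PROXIMAL_FRACTION = 0.07


@dataclass(frozen=True)
class WK3Params:
    """One branch's Windkessel constants (SI units)."""

    Rp: float  # proximal resistance, Pa s m^-3
    Rd: float  # distal resistance, Pa s m^-3
    C: float  # compliance, m^3 Pa^-1

    def __post_init__(self) -> None:
        if min(self.Rp, self.Rd, self.C) <= 0:
            raise ValueError("Rp, Rd and C must all be strictly positive")

    @property
    def series_resistance(self) -> float:
        return self.Rp + self.Rd

    @property
    def time_constant(self) -> float:
        """Capacitor decay time constant Rd*C, s."""
        return self.Rd * self.C


@dataclass
class SystemicState:
    """Systemic haemodynamic state used to size the outlet network."""

    sbp: float = 78.0  # systolic pressure, mmHg
    dbp: float = 69.0  # diastolic pressure, mmHg
    map: float = 73.0  # mean arterial pressure, mmHg
    co: float = 6.7e-5  # cardiac output, m^3/s
    hr: float = 30.0  # heart rate, BPM
    distensibility: float = 7.9e-3  # relative aortic distensibility, mmHg^-1
    reference_volume: float | None = None  # m^3; None -> default total compliance

    def __post_init__(self) -> None:
        if not self.dbp < self.map < self.sbp:
            raise ValueError("pressures must satisfy dbp < map < sbp")
        if self.co <= 0:
            raise ValueError("cardiac output must be strictly positive")

    @property
    def total_resistance(self) -> float:
        """MAP/CO in SI units, Pa s m^-3."""
        return self.map * MMHG_TO_PA / self.co

    @property
    def total_compliance(self) -> float:
        """Total arterial compliance, m^3/Pa.

        Derived as distensibility (converted to Pa^-1) times the reference
        volume when one is given; otherwise the shipped-table total.
        """
        if self.reference_volume is None:
            return DEFAULT_TOTAL_COMPLIANCE
        return (self.distensibility / MMHG_TO_PA) * self.reference_volume


@dataclass(frozen=True)
class BranchSpec:
    """A named outlet and its share of the cardiac output."""

    name: str
    flow_fraction: float

    def __post_init__(self) -> None:
        if self.flow_fraction <= 0:
            raise ValueError(
                f"branch {self.name!r}: flow_fraction must be > 0 "
                "(zero flow implies infinite resistance)"
            )


def wk3_response(
    params: WK3Params,
    inflow: Callable[[float], float] | float,
    pc0: float,
    duration: float,
    dt: float = 1e-3,
    method: str = "rk4",
):
    """Integrate one Windkessel branch driven by a prescribed inflow.

    Parameters
    ----------
    inflow : callable or float
        Branch flow Q(t) in m^3/s (a constant is promoted to a constant
        function).
    pc0 : float
        Initial capacitor pressure, Pa.
    method : {"rk4", "implicit_euler"}
        Fixed-step classic Runge-Kutta (default) or implicit Euler for
        stiff parameter sets.

    Returns
    -------
    t, p, pc : ndarray
        Sample times, branch inlet pressure ``Pc + Q*Rp`` and capacitor
        pressure, all of length ``round(duration/dt) + 1``.
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    q = inflow if callable(inflow) else (lambda _t, _q=float(inflow): _q)
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    pc = np.empty(n + 1)
    pc[0] = pc0
    tau_inv = 1.0 / (params.Rd * params.C)
    c_inv = 1.0 / params.C

    def dpc(ti: float, pci: float) -> float:
        return q(ti) * c_inv - pci * tau_inv

    if method == "rk4":
        for i in range(n):
            ti, yi = t[i], pc[i]
            k1 = dpc(ti, yi)
            k2 = dpc(ti + dt / 2, yi + dt / 2 * k1)
            k3 = dpc(ti + dt / 2, yi + dt / 2 * k2)
            k4 = dpc(ti + dt, yi + dt * k3)
            pc[i + 1] = yi + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    elif method == "implicit_euler":
        for i in range(n):
            # linear ODE: pc' = Q/C - pc/tau -> exact implicit update
            pc[i + 1] = (pc[i] + dt * q(t[i + 1]) * c_inv) / (1.0 + dt * tau_inv)
    else:
        raise ValueError(f"unknown method {method!r}")
    qs = np.array([q(ti) for ti in t])
    p = pc + qs * params.Rp
    return t, p, pc


def estimate_rcr(
    systemic: SystemicState,
    branches: list[BranchSpec],
    proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION,
) -> dict[str, WK3Params]:
    """Size per-branch RCR constants from systemic haemodynamics.

    The branches form a parallel circuit: the total resistance MAP/CO is
    apportioned inversely to each branch's flow fraction, split into
    proximal and distal parts, and the total compliance is apportioned
    proportionally to flow fraction.
    """
    if not branches:
        raise ValueError("at least one branch is required")
    if not 0.0 < proximal_fraction < 1.0:
        raise ValueError("proximal_fraction must lie strictly in (0, 1)")
    fractions = np.array([b.flow_fraction for b in branches])
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"flow fractions must sum to 1, got {fractions.sum():.12f}")
    r_total = systemic.total_resistance
    c_total = systemic.total_compliance
    out: dict[str, WK3Params] = {}
    for b in branches:
        r_i = r_total / b.flow_fraction
        out[b.name] = WK3Params(
            Rp=proximal_fraction * r_i,
            Rd=(1.0 - proximal_fraction) * r_i,
            C=b.flow_fraction * c_total,
        )
    return out


def total_parallel_resistance(params_map: Mapping[str, WK3Params]) -> float:
    """Equivalent resistance of the parallel outlet circuit, Pa s m^-3."""
    if not params_map:
        raise ValueError("params_map must be non-empty")
    conductance = sum(1.0 / p.series_resistance for p in params_map.values())
    return 1.0 / conductance


def _table3_frame() -> pd.DataFrame:
    with resources.files("graftflow.data").joinpath("table3_windkessel.csv").open() as f:
        return pd.read_csv(f)


def table3_branches() -> dict[str, WK3Params]:
    """The packaged seven-outlet RCR set (ordered as shipped)."""
    df = _table3_frame()
    return {
        row["name"]: WK3Params(Rp=row["Rp"], Rd=row["Rd"], C=row["C"])
        for _, row in df.iterrows()
    }

def table3_flow_fractions() -> list[BranchSpec]:
    """Flow fractions implied by the packaged table (conductance shares)."""
    params = table3_branches()
    g = {name: 1.0 / p.series_resistance for name, p in params.items()}
    g_sum = sum(g.values())
    return [BranchSpec(name=n, flow_fraction=gi / g_sum) for n, gi in g.items()]
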