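"""Lumped (0D) simulator of the LVAD-supported aortic flow network.

The aorta is collapsed to a single pressure node: the outflow-graft and
aortic-root inflows feed the node, and the seven Windkessel outlets drain
it. With the rigid-wall assumption there is no storage at the node
itself, so at every instant the node pressure follows algebraically from
the inflow and the capacitor pressures:

    P = (q_in + sum_i Pc_i/Rp_i) / (sum_i 1/Rp_i),   q_i = (P - Pc_i)/Rp_i

and mass is conserved exactly by construction. The capacitor states are
advanced with fixed-step classic Runge-Kutta, and the run is declared
periodically converged when the relative L2 distance between consecutive
pump cycles of the node pressure falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from graftflow.constants import MMHG_TO_PA
from graftflow.waveforms import InletProgram, combined_inlet
from graftflow.windkessel import WK3Params

__all__ = [
    "Network",
    "SolverConfig",
    "SimulationResult",
    "node_pressure",
    "simulate",
    "summarize",
]


@dataclass
class Network:
    """The outlet network drained from one aortic pressure node."""

    branches: dict[str, WK3Params]
    node_label: str = "aorta"

    def __post_init__(self) -> None:
        if not self.branches:
            raise ValueError("network needs at least one branch")


@dataclass
class SolverConfig:
    dt: float = 1e-3  # s
    n_cycles: int = 20  # maximum pump cycles to run
    convergence_tol: float = 1e-3  # relative cycle-to-cycle L2 change
    min_cycles: int = 2  # cycles to run before testing convergence

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")


@dataclass
class SimulationResult:
    """Time series produced by :func:`simulate` (SI units)."""

    t: np.ndarray
    p_node: np.ndarray
    q_branch: dict[str, np.ndarray]
    pc_branch: dict[str, np.ndarray]
    q_in: np.ndarray
    converged: bool
    cycles_run: int
    cycle_period: float

    def to_csv(self, path: str | Path) -> None:
        cols = {"t": self.t, "p_node": self.p_node, "q_in": self.q_in}
        cols.update({f"q_{k}": v for k, v in self.q_branch.items()})
        pd.DataFrame(cols).to_csv(path, index=False)


def node_pressure(q_in: float, pc: np.ndarray, rp: np.ndarray):
    """Algebraic node pressure and branch flows of the parallel circuit.

    Returns ``(P, q)`` with ``sum(q) == q_in`` to machine precision.
    """
    pc = np.asarray(pc, dtype=float)
    rp = np.asarray(rp, dtype=float)
    if pc.size == 0:
        raise ValueError("at least one branch is required")
    if np.any(rp <= 0):
        raise ValueError("all proximal resistances must be strictly positive")
    g = 1.0 / rp
    p = (q_in + np.sum(pc * g)) / np.sum(g)
    q = (p - pc) * g
    return p, q


def simulate(
    network: Network, program: InletProgram, config: SolverConfig
) -> SimulationResult:
    """Run the 0D network under the combined inlet program.

    Integrates until the cycle-to-cycle node-pressure change drops below
    ``config.convergence_tol`` or ``config.n_cycles`` pump cycles elapse.
    Raises ``FloatingPointError`` with time-step advice if the state
    becomes non-finite.
    """
    names = list(network.branches)
    rp = np.array([network.branches[n].Rp for n in names])
    rd = np.array([network.branches[n].Rd for n in names])
    c = np.array([network.branches[n].C for n in names])
    tau_inv = 1.0 / (rd * c)
    c_inv = 1.0 / c

    period = program.og_period
    steps_per_cycle = int(round(period / config.dt))
    dt = period / steps_per_cycle  # snap dt so cycles tile exactly

    def q_total(t: float) -> float:
        og, av = combined_inlet(program, t)
        return og + av

    def rhs(t: float, pc: np.ndarray) -> np.ndarray:
        _, q = node_pressure(q_total(t), pc, rp)
        return q * c_inv - pc * tau_inv

    pc = np.zeros(len(names))
    t_list = [0.0]
    pc_hist = [pc.copy()]
    converged = False
    cycles_run = 0
    prev_cycle: np.ndarray | None = None
    p0, q0 = node_pressure(q_total(0.0), pc, rp)
    p_list = [p0]

    for cycle in range(config.n_cycles):
        cycle_p = np.empty(steps_per_cycle)
        for i in range(steps_per_cycle):
            t = cycle * period + i * dt
            k1 = rhs(t, pc)
            k2 = rhs(t + dt / 2, pc + dt / 2 * k1)
            k3 = rhs(t + dt / 2, pc + dt / 2 * k2)
            k4 = rhs(t + dt, pc + dt * k3)
            pc = pc + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.all(np.isfinite(pc)):
                raise FloatingPointError(
                    f"non-finite capacitor state at t={t + dt:.4f} s "
                    f"(cycle {cycle + 1}, step {i + 1}); reduce dt below "
                    f"{dt:.1e} s or use stiffer-friendly parameters"
                )
            tn = t + dt
            p, _ = node_pressure(q_total(tn), pc, rp)
            t_list.append(tn)
            pc_hist.append(pc.copy())
            p_list.append(p)
            cycle_p[i] = p
        cycles_run = cycle + 1
        if prev_cycle is not None and cycles_run >= config.min_cycles:
            denom = np.linalg.norm(prev_cycle)
            change = np.linalg.norm(cycle_p - prev_cycle) / (denom if denom else 1.0)
            if change < config.convergence_tol:
                converged = True
                prev_cycle = cycle_p
                break
        prev_cycle = cycle_p

    t_arr = np.array(t_list)
    pc_arr = np.array(pc_hist)  # (n_t, n_branch)
    q_in = np.array([q_total(ti) for ti in t_arr])
    p_arr = np.array(p_list)
    g = 1.0 / rp
    q_arr = (p_arr[:, None] - pc_arr) * g[None, :]
    return SimulationResult(
        t=t_arr,
        p_node=p_arr,
        q_branch={n: q_arr[:, j] for j, n in enumerate(names)},
        pc_branch={n: pc_arr[:, j] for j, n in enumerate(names)},
        q_in=q_in,
        converged=converged,
        cycles_run=cycles_run,
        cycle_period=period,
    )


def summarize(result: SimulationResult, cycle_period: float | None = None) -> dict:
    """Cycle summary of the final full pump cycle.

    Returns mean/max/min node pressure (Pa and mmHg), per-branch
    cycle-mean flows and flow fractions, and the outflow volume per
    cycle.
    """
    period = cycle_period if cycle_period is not None else result.cycle_period
    dt = result.t[1] - result.t[0]
    n_cycle = int(round(period / dt))
    if result.t.size - 1 < n_cycle:
        raise ValueError("result spans less than one full cycle")
    sl = slice(result.t.size - n_cycle - 1, result.t.size)
    t = result.t[sl]
    p = result.p_node[sl]
    p_mean = float(np.trapezoid(p, t) / period)
    q_means = {
        name: float(np.trapezoid(q[sl], t) / period)
        for name, q in result.q_branch.items()
    }
    q_total_mean = sum(q_means.values())
    fractions = {name: qm / q_total_mean for name, qm in q_means.items()}
    return {
        "pressure_mean_pa": p_mean,
        "pressure_max_pa": float(p.max()),
        "pressure_min_pa": float(p.min()),
        "pressure_mean_mmhg": p_mean / MMHG_TO_PA,
        "pressure_max_mmhg": float(p.max()) / MMHG_TO_PA,
        "pressure_min_mmhg": float(p.min()) / MMHG_TO_PA,
        "branch_mean_flow_m3s": q_means,
        "branch_flow_fraction": fractions,
        "outflow_volume_per_cycle_m3": q_total_mean * period,
        "converged": result.converged,
        "cycles_run": result.cycles_run,
    }
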