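"""End-to-end study orchestration.

``run_study`` reproduces the desk-scale chain: synthesize the inlet
program (artificial-pulse OG flow + residual native cycle), build or
load the Windkessel outlet network, run the 0D simulator to periodic
convergence, summarize pressures and branch flows, and enumerate the
anastomosis-geometry study set. All outputs land in a run directory with
a serialized config, a checksummed file manifest, and convergence
diagnostics in the log; a re-run with the same config reproduces the
summary byte-for-byte (the solver is fixed-step and deterministic).

Internal computation is SI-only; pressures are reported in both Pa and
mmHg.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from graftflow.aortic_network import Network, SolverConfig, simulate, summarize
from graftflow.graft_geometry import enumerate_configurations
from graftflow.waveforms import (
    InletProgram,
    PulseSchedule,
    native_hf_waveform,
    og_flow_waveform,
)
from graftflow.windkessel import (
    BranchSpec,
    SystemicState,
    estimate_rcr,
    table3_branches,
)

__all__ = ["RunConfig", "run_study"]

logger = logging.getLogger(__name__)

_ALLOWED_KEYS = {
    "systemic",
    "branches",
    "schedule",
    "program",
    "solver",
    "out_dir",
    "native_cardiac_output",
    "native_period",
    "systolic_fraction",
}


@dataclass
class RunConfig:
    """Fully-specified study configuration."""

    systemic: SystemicState = field(default_factory=SystemicState)
    branches: str | list[BranchSpec] = "table3"
    schedule: PulseSchedule = field(default_factory=PulseSchedule)
    program: dict = field(
        default_factory=lambda: {
            "residual_fraction": 0.05,
            "opening_interval": 5,
            "av_open": True,
        }
    )
    solver: SolverConfig = field(default_factory=SolverConfig)
    out_dir: str = "graftflow_run"
    native_cardiac_output: float = 5.33e-5  # m^3/s, ~3.2 L/min
    native_period: float = 0.7  # s
    systolic_fraction: float = 0.35

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(self.branches, str):
            d["branches"] = [dataclasses.asdict(b) for b in self.branches]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        bad = set(d) - _ALLOWED_KEYS
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        kwargs = dict(d)
        if "systemic" in kwargs and isinstance(kwargs["systemic"], dict):
            kwargs["systemic"] = SystemicState(**kwargs["systemic"])
        if "schedule" in kwargs and isinstance(kwargs["schedule"], dict):
            sched = dict(kwargs["schedule"])
            if "speed_band" in sched:
                sched["speed_band"] = tuple(sched["speed_band"])
            kwargs["schedule"] = PulseSchedule(**sched)
        if "solver" in kwargs and isinstance(kwargs["solver"], dict):
            kwargs["solver"] = SolverConfig(**kwargs["solver"])
        branches = kwargs.get("branches", "table3")
        if not isinstance(branches, str):
            kwargs["branches"] = [
                b if isinstance(b, BranchSpec) else BranchSpec(**b) for b in branches
            ]
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig) -> Path:
    """Execute the full study; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    og = og_flow_waveform(config.schedule, mean_flow=config.systemic.co)
    native = native_hf_waveform(
        config.native_cardiac_output,
        period=config.native_period,
        systolic_fraction=config.systolic_fraction,
    )
    program = InletProgram(
        og=og, native=native, og_period=config.schedule.period, **config.program
    )

    if config.branches == "table3":
        branch_params = table3_branches()
    elif isinstance(config.branches, str):
        raise ValueError(f"unknown branch set {config.branches!r}")
    else:
        branch_params = estimate_rcr(config.systemic, config.branches)
    network = Network(branches=branch_params)

    result = simulate(network, program, config.solver)
    logger.info(
        "simulation %s after %d cycles (dt=%.0e s)",
        "converged" if result.converged else "did NOT converge",
        result.cycles_run,
        config.solver.dt,
    )
    summary = summarize(result)
    logger.info(
        "cycle-mean node pressure %.1f mmHg; branch fractions sum %.12f",
        summary["pressure_mean_mmhg"],
        sum(summary["branch_flow_fraction"].values()),
    )

    geometry = [
        {"d": p.d, "side": p.side, "angle": p.angle, "og_diameter": p.og_diameter}
        for p in enumerate_configurations()
    ]

    og.to_json(out / "og_waveform.json")
    native.to_json(out / "native_waveform.json")
    with open(out / "network.csv", "w") as f:
        f.write("name,Rp,Rd,C\n")
        for name, p in branch_params.items():
            f.write(f"{name},{p.Rp!r},{p.Rd!r},{p.C!r}\n")
    result.to_csv(out / "result.csv")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "geometry_manifest.json").write_text(json.dumps(geometry, indent=2))
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
    files = [
        "og_waveform.json",
        "native_waveform.json",
        "network.csv",
        "result.csv",
        "summary.json",
        "geometry_manifest.json",
        "config.json",
    ]
    manifest = {name: _sha256(out / name) for name in files}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
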