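"""Run-configuration schema, readers/writers and fixture generation.

A run is described by one human-readable YAML file with four sections
(``sources``, ``allocation``, ``network``, ``run`` and an optional
``metrics`` window policy).  A ``case`` shorthand expands to the full
parameterization of the built-in reference cases A-E.  Schemas are
validated with pydantic before any simulation; unknown keys are
rejected.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import cases
from .network import (
    Compartment,
    Conduit,
    HydraulicNetwork,
    OutletAttachment,
    TimeSeriesResult,
)
from .waveforms import InletSource
from .windkessel import (
    ComplianceFit,
    OutletAllocation,
    WindkesselOutlet,
    allocate_compliances,
    allocate_resistances,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "write_case_fixtures",
    "write_timeseries",
    "read_timeseries",
    "write_tuning_summary",
    "write_tuning_curve",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SourceSpec(_StrictModel):
    name: str
    node: str
    mean: float = 0.0
    amplitude: float = Field(default=0.0, ge=0.0)
    frequency: float = Field(default=0.0, ge=0.0)
    phase: float = 0.0

    def build(self) -> InletSource:
        return InletSource(
            self.name, self.node,
            mean_flow=self.mean, amplitude=self.amplitude,
            frequency=self.frequency, phase=self.phase,
        )


class AllocationSpec(_StrictModel):
    R_tot: float = Field(gt=0.0)
    C_tot: float = Field(ge=0.0)
    outflow_fractions: Dict[str, float]
    compliance_fractions: Dict[str, float]
    ICP_avg: float = 10.0
    Q_production: float = 6.67e-3

    @field_validator("outflow_fractions")
    @classmethod
    def _outflow_sum(cls, v: Dict[str, float]) -> Dict[str, float]:
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outflow_fractions must sum to 1, got {total!r} from {v!r}")
        return v

    @field_validator("compliance_fractions")
    @classmethod
    def _compliance_sum(cls, v: Dict[str, float]) -> Dict[str, float]:
        if any(ci < 0 for ci in v.values()):
            raise ValueError(f"compliance_fractions must be >= 0, got {v!r}")
        total = sum(v.values())
        if v and abs(total - 1.0) > 1e-9:
            raise ValueError(f"compliance_fractions must sum to 1, got {total!r} from {v!r}")
        return v

    def build(self) -> OutletAllocation:
        return OutletAllocation(
            R_tot=self.R_tot, C_tot=self.C_tot,
            q=dict(self.outflow_fractions), c=dict(self.compliance_fractions),
            ICP_avg=self.ICP_avg, Q_production=self.Q_production,
        )


class ConduitSpec(_StrictModel):
    name: str
    upstream: str
    downstream: str
    length_mm: Optional[float] = Field(default=None, gt=0.0)
    area_mm2: Optional[float] = Field(default=None, gt=0.0)
    resistance: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _geometry_or_resistance(self) -> "ConduitSpec":
        if self.resistance is None and (self.length_mm is None or self.area_mm2 is None):
            raise ValueError(
                f"conduit {self.name!r}: give either an explicit resistance or "
                "both length_mm and area_mm2"
            )
        return self

    def build(self) -> Conduit:
        if self.resistance is not None:
            return Conduit(
                self.name, self.upstream, self.downstream,
                self.resistance, self.area_mm2,
            )
        return Conduit.from_geometry(
            self.name, self.upstream, self.downstream, self.length_mm, self.area_mm2
        )


class OutletPlacement(_StrictModel):
    name: str
    node: str
    P_out: float = 0.0


class NetworkSpec(_StrictModel):
    compartments: List[str]
    conduits: List[ConduitSpec]
    outlets: List[OutletPlacement]


class RunSettings(_StrictModel):
    dt: float = Field(default=0.05, gt=0.0)
    duration: float = Field(default=25.0, gt=0.0)
    solver: Literal["monolithic", "partitioned"] = "monolithic"
    initial_pressure: float = 10.0
    tol: float = Field(default=1e-9, gt=0.0)
    max_iter: int = Field(default=50, ge=1)


class MetricsSpec(_StrictModel):
    # default: last 5 s of the run
    window_seconds: float = Field(default=5.0, gt=0.0)


class RunConfig(_StrictModel):
    """Fully expanded, validated description of one simulation run."""

    case: Optional[str] = None
    sources: List[SourceSpec]
    allocation: AllocationSpec
    network: NetworkSpec
    run: RunSettings = RunSettings()
    metrics: MetricsSpec = MetricsSpec()

    @model_validator(mode="after")
    def _referential_integrity(self) -> "RunConfig":
        nodes = set(self.network.compartments)
        for s in self.sources:
            if s.node not in nodes:
                raise ValueError(f"source {s.name!r} references unknown compartment {s.node!r}")
        for o in self.network.outlets:
            if o.node not in nodes:
                raise ValueError(f"outlet {o.name!r} references unknown compartment {o.node!r}")
        alloc_names = set(self.allocation.outflow_fractions)
        placed = {o.name for o in self.network.outlets}
        if alloc_names != placed:
            raise ValueError(
                f"allocation outlets {sorted(alloc_names)} do not match placed "
                f"outlets {sorted(placed)}"
            )
        return self

    @classmethod
    def from_case(cls, case_id: str) -> "RunConfig":
        """Expand a reference case id into its full parameterization."""
        case, net = cases.build_case(case_id)
        return cls(
            case=case_id,
            sources=[
                SourceSpec(
                    name=s.name, node=s.node, mean=s.mean_flow,
                    amplitude=s.amplitude, frequency=s.frequency, phase=s.phase,
                )
                for s in case.sources
            ],
            allocation=AllocationSpec(
                R_tot=case.allocation.R_tot,
                C_tot=case.allocation.C_tot,
                outflow_fractions=dict(case.allocation.q),
                compliance_fractions=dict(case.allocation.c),
                ICP_avg=case.allocation.ICP_avg,
                Q_production=case.allocation.Q_production,
            ),
            network=NetworkSpec(
                compartments=list(net.node_names),
                conduits=[
                    ConduitSpec(
                        name=c.name, upstream=c.upstream, downstream=c.downstream,
                        resistance=c.resistance, area_mm2=c.area_mm2,
                    )
                    for c in net.conduits
                ],
                outlets=[
                    OutletPlacement(name=a.outlet.name, node=a.node, P_out=a.outlet.P_out)
                    for a in net.outlets
                ],
            ),
        )

    def build_network(self) -> HydraulicNetwork:
        allocation = self.allocation.build()
        resistances = allocate_resistances(allocation)
        compliances = allocate_compliances(allocation)
        return HydraulicNetwork(
            compartments=tuple(Compartment(n) for n in self.network.compartments),
            conduits=tuple(c.build() for c in self.network.conduits),
            sources=tuple(s.build() for s in self.sources),
            outlets=tuple(
                OutletAttachment(
                    WindkesselOutlet(
                        o.name,
                        R=resistances[o.name],
                        C=compliances.get(o.name, 0.0),
                        P_out=o.P_out,
                    ),
                    o.node,
                )
                for o in self.network.outlets
            ),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    A file containing only ``case: <id>`` (plus optional ``run`` /
    ``metrics`` overrides) is expanded to the full reference-case
    parameterization.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    if "case" in data and "sources" not in data:
        base = RunConfig.from_case(data["case"]).model_dump()
        for key, value in data.items():
            if key != "case":
                base[key] = value
        data = base
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=False)
    )


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical serialized configuration."""
    canonical = yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_case_fixtures(outdir: str | Path) -> List[Path]:
    """Write the five reference-case configurations as YAML files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for case_id in cases.CASE_IDS:
        path = outdir / f"case{case_id}.yaml"
        save_config(RunConfig.from_case(case_id), path)
        paths.append(path)
    return paths


def write_timeseries(result: TimeSeriesResult, path: str | Path) -> None:
    """Write a run trace as CSV: time, node pressures, conduit and outlet flows.

    Floats are written in shortest round-trip representation, so
    re-running an identical configuration produces a byte-identical
    file.
    """
    frame = result.to_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty time series")
    frame.to_csv(path, index=False)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_tuning_summary(fit: ComplianceFit, path: str | Path) -> None:
    """Small structured record of a compliance fit."""
    Path(path).write_text(
        yaml.safe_dump(
            {
                "fitted_C_tot_ml_per_mmHg": fit.c_tot,
                "target_amplitude_mmHg": fit.target_amplitude,
                "achieved_amplitude_mmHg": fit.achieved_amplitude,
                "grid": {
                    "min": float(fit.grid[0]),
                    "max": float(fit.grid[-1]),
                    "n": int(fit.grid.size),
                },
            },
            sort_keys=False,
        )
    )


def write_tuning_curve(fit: ComplianceFit, path: str | Path) -> None:
    """Amplitude-versus-compliance curve of a fit, as CSV."""
    pd.DataFrame(
        {"C_tot_ml_per_mmHg": fit.grid, "amplitude_mmHg": fit.amplitudes}
    ).to_csv(path, index=False)
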