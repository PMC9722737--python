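"""Reference simulation cases A-E and their report metrics.

The five cases share the inlet sources (constant production 6.67e-3
ml/s, cardiac sinusoids of 0.11 and 5.05 ml/s at 1 Hz, respiratory
sinusoid of 1.01 ml/s at 0.2 Hz) and the outflow split (20/20/30/30 %
over the interstitial, spinal, lymphatic and arachnoid-villi outlets at
R_tot = 1500 mmHg·s/ml); they differ in whether respiration is active,
in how the compliance is distributed over the outlets, and in the total
compliance:

    A - no respiration;   c = (int 33, sp 67, lym 0,  av 0) %, C_tot 0.17
    B - respiration on;   c as A,                            C_tot 0.51
    C - respiration on;   c = (11, 67, 11, 11) %,            C_tot 0.51
    D - respiration on;   c = (67, 33, 0, 0) % (A reversed), C_tot 0.51
    E - as B with total compliance raised to 1.01 ml/mmHg.

Only case A's total compliance comes out of the 0D tuning procedure;
the remaining values are taken as case inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .network import (
    Compartment,
    Conduit,
    FluidProperties,
    HydraulicNetwork,
    OutletAttachment,
    TimeSeriesResult,
    WATER,
    run,
)
from .waveforms import InletSource
from .windkessel import (
    OutletAllocation,
    WindkesselOutlet,
    ZeroDModel,
    allocate_compliances,
    allocate_resistances,
    pulsation_amplitude,
)

__all__ = [
    "CASE_IDS",
    "CaseDefinition",
    "CaseMetrics",
    "case_definition",
    "build_case",
    "zero_d_model",
    "compute_metrics",
    "run_case",
]

CASE_IDS = ("A", "B", "C", "D", "E")

# inlet source parameters (ml/s, Hz)
PRODUCTION_MEAN = 6.67e-3
ARTERIAL1_AMPLITUDE = 0.11
ARTERIAL2_AMPLITUDE = 5.05
VENOUS1_AMPLITUDE = 1.01
CARDIAC_FREQUENCY = 1.0
RESPIRATORY_FREQUENCY = 0.2

# outlet parameters
R_TOT = 1500.0
OUTFLOW_FRACTIONS: Dict[str, float] = {"int": 0.20, "sp": 0.20, "lym": 0.30, "av": 0.30}
ICP_TARGET = 10.0

_COMPLIANCE_FRACTIONS: Dict[str, Dict[str, float]] = {
    "A": {"int": 0.33, "sp": 0.67, "lym": 0.0, "av": 0.0},
    "B": {"int": 0.33, "sp": 0.67, "lym": 0.0, "av": 0.0},
    "C": {"int": 0.11, "sp": 0.67, "lym": 0.11, "av": 0.11},
    "D": {"int": 0.67, "sp": 0.33, "lym": 0.0, "av": 0.0},
    "E": {"int": 0.33, "sp": 0.67, "lym": 0.0, "av": 0.0},
}
_C_TOT: Dict[str, float] = {"A": 0.17, "B": 0.51, "C": 0.51, "D": 0.51, "E": 1.01}

# default conduit geometry (mm, mm^2)
AQUEDUCT_LENGTH_MM = 15.0
AQUEDUCT_AREA_MM2 = 10.0
CHANNEL_LENGTH_MM = 30.0
CHANNEL_AREA_MM2 = 150.0

# clinical reference bands (mmHg)
PHYSIOLOGICAL_RANGE = (7.0, 15.0)
TBI_THRESHOLD = 22.0


@dataclass(frozen=True)
class CaseDefinition:
    """Inlet sources plus outlet allocation for one reference case."""

    id: str
    sources: Tuple[InletSource, ...]
    allocation: OutletAllocation


def case_definition(case_id: str) -> CaseDefinition:
    """Parameters of reference case ``case_id`` (one of A-E)."""
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case {case_id!r}; expected one of {CASE_IDS}")
    sources = [
        InletSource("production", "ventricles", mean_flow=PRODUCTION_MEAN),
        InletSource(
            "arterial1", "ventricles",
            amplitude=ARTERIAL1_AMPLITUDE, frequency=CARDIAC_FREQUENCY,
        ),
        InletSource(
            "arterial2", "basilar",
            amplitude=ARTERIAL2_AMPLITUDE, frequency=CARDIAC_FREQUENCY,
        ),
    ]
    if case_id != "A":
        sources.append(
            InletSource(
                "venous1", "cranialSAS",
                amplitude=VENOUS1_AMPLITUDE, frequency=RESPIRATORY_FREQUENCY,
            )
        )
    allocation = OutletAllocation(
        R_tot=R_TOT,
        C_tot=_C_TOT[case_id],
        q=dict(OUTFLOW_FRACTIONS),
        c=dict(_COMPLIANCE_FRACTIONS[case_id]),
        ICP_avg=ICP_TARGET,
        Q_production=PRODUCTION_MEAN,
    )
    return CaseDefinition(case_id, tuple(sources), allocation)


def _default_network(case: CaseDefinition, fluid: FluidProperties = WATER) -> HydraulicNetwork:
    """Default four-compartment topology with the case's outlets attached.

    ventricles -aqueduct-> basilar -tentorial-> cranialSAS and
    basilar -foramen_magnum-> spinalSAS; interstitial, lymphatic and
    arachnoid-villi outlets drain the cranial SAS, the spinal outlet the
    spinal SAS.  Conduit resistances are Poiseuille values on water for
    the default lengths/areas.
    """
    resistances = allocate_resistances(case.allocation)
    compliances = allocate_compliances(case.allocation)
    outlet_node = {"int": "cranialSAS", "sp": "spinalSAS", "lym": "cranialSAS", "av": "cranialSAS"}
    outlets = tuple(
        OutletAttachment(
            WindkesselOutlet(name, R=resistances[name], C=compliances.get(name, 0.0)),
            outlet_node[name],
        )
        for name in ("int", "sp", "lym", "av")
    )
    return HydraulicNetwork(
        compartments=tuple(
            Compartment(n) for n in ("ventricles", "basilar", "cranialSAS", "spinalSAS")
        ),
        conduits=(
            Conduit.from_geometry(
                "aqueduct", "ventricles", "basilar",
                AQUEDUCT_LENGTH_MM, AQUEDUCT_AREA_MM2, fluid,
            ),
            Conduit.from_geometry(
                "tentorial", "basilar", "cranialSAS",
                CHANNEL_LENGTH_MM, CHANNEL_AREA_MM2, fluid,
            ),
            Conduit.from_geometry(
                "foramen_magnum", "basilar", "spinalSAS",
                CHANNEL_LENGTH_MM, CHANNEL_AREA_MM2, fluid,
            ),
        ),
        sources=case.sources,
        outlets=outlets,
    )


def build_case(
    case_id: str, fluid: FluidProperties = WATER
) -> Tuple[CaseDefinition, HydraulicNetwork]:
    """Case definition plus the default network configured for it."""
    case = case_definition(case_id)
    return case, _default_network(case, fluid)


def zero_d_model(case_id: str, dt: float = 0.05, P0: float = 0.0) -> ZeroDModel:
    """Single-node model with the case's combined inflow (for tuning)."""
    case = case_definition(case_id)
    return ZeroDModel(
        R_tot=case.allocation.R_tot,
        C_tot=case.allocation.C_tot,
        inflow=case.sources,
        dt=dt,
        P0=P0,
    )


@dataclass(frozen=True)
class CaseMetrics:
    """Report metrics of one run, evaluated over a steady-cycle window."""

    case_id: str
    window: Tuple[float, float]
    mean_pressure: Dict[str, float]  # per compartment, mmHg
    pressure_pulsation_amplitude: float  # cranial SAS, mmHg
    aqueduct_flow_amplitude: float  # ml/s
    spinal_flow_amplitude: float  # foramen magnum conduit, ml/s
    lv_to_sas_pressure_difference_amplitude: float  # mmHg
    outlet_flow_amplitudes: Dict[str, float]  # ml/s
    mean_aqueduct_flow: float  # ml/s
    mean_outlet_flow_total: float  # ml/s
    peak_aqueduct_velocity: float  # cm/s
    in_physiological_range: bool
    below_tbi_threshold: bool


def compute_metrics(
    result: TimeSeriesResult,
    case: CaseDefinition,
    window: Tuple[float, float],
    aqueduct_area_mm2: float = AQUEDUCT_AREA_MM2,
) -> CaseMetrics:
    """Evaluate the report metrics over ``window`` (s).

    Means are taken over the half-open interval ``(t0, t1]`` so that a
    window spanning whole source periods at the sampling step contains
    an exact number of samples per period (pulsatile means then vanish
    to round-off).  Amplitudes are half peak-to-peak over the window;
    the ventricle-to-spinal-SAS pressure difference is evaluated on the
    pointwise difference trace.  Peak aqueduct velocity is the largest
    absolute aqueduct flow divided by the aqueduct cross-section.
    """
    t0, t1 = window
    t = result.time
    if t0 >= t1 or t1 > t[-1] + 1e-9:
        raise ValueError(f"window {window} outside simulated span (0, {t[-1]}]")
    mean_mask = (t > t0 + 1e-12) & (t <= t1 + 1e-12)
    if not np.any(mean_mask):
        raise ValueError(f"window {window} selects no samples")

    def amp(values: np.ndarray) -> float:
        return pulsation_amplitude(t, values, window)

    mean_pressure = {
        name: float(result.pressure(name)[mean_mask].mean()) for name in result.node_names
    }
    p_cranial = result.pressure("cranialSAS")
    q_aqueduct = result.conduit_flow("aqueduct")
    q_spinal = result.conduit_flow("foramen_magnum")
    p_diff = result.pressure("ventricles") - result.pressure("spinalSAS")
    peak_velocity = float(
        np.max(np.abs(q_aqueduct[mean_mask])) / (aqueduct_area_mm2 / 100.0)
    )
    mean_cranial = mean_pressure["cranialSAS"]
    return CaseMetrics(
        case_id=case.id,
        window=(float(t0), float(t1)),
        mean_pressure=mean_pressure,
        pressure_pulsation_amplitude=amp(p_cranial),
        aqueduct_flow_amplitude=amp(q_aqueduct),
        spinal_flow_amplitude=amp(q_spinal),
        lv_to_sas_pressure_difference_amplitude=amp(p_diff),
        outlet_flow_amplitudes={
            name: amp(result.outlet_flow(name)) for name in result.outlet_names
        },
        mean_aqueduct_flow=float(q_aqueduct[mean_mask].mean()),
        mean_outlet_flow_total=float(result.outlet_flows[mean_mask].sum(axis=1).mean()),
        peak_aqueduct_velocity=peak_velocity,
        in_physiological_range=bool(
            PHYSIOLOGICAL_RANGE[0] <= mean_cranial <= PHYSIOLOGICAL_RANGE[1]
        ),
        below_tbi_threshold=bool(np.max(p_cranial[mean_mask]) < TBI_THRESHOLD),
    )


def run_case(
    case_id: str,
    duration: float = 25.0,
    dt: float = 0.05,
    solver: str = "monolithic",
    initial_pressure: float = 10.0,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> Tuple[TimeSeriesResult, CaseMetrics]:
    """Run a reference case and evaluate its metrics.

    Outlet states (and hence the effective initial node pressures) start
    at ``initial_pressure``; the default is the 10 mmHg target mean, so
    the slow mean transient (time constant R_tot·C_tot of minutes) does
    not dominate a 25 s run.  The metrics window is the last 5 s of the
    run: five cardiac cycles for case A, one full respiratory cycle
    (which is also five cardiac cycles) for cases B-E.
    """
    case, net = build_case(case_id)
    result = run(
        net,
        dt=dt,
        duration=duration,
        solver=solver,
        initial_pressures=initial_pressure,
        tol=tol,
        max_iter=max_iter,
    )
    window = (max(duration - 5.0, 0.0), duration)
    return result, compute_metrics(result, case, window)
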