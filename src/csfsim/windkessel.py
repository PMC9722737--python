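"""Two-element windkessel outlets, parameter allocation and 0D tuning.

Each CSF absorption pathway (interstitial ``int``, spinal ``sp``,
lymphatic ``lym``, arachnoid-villi ``av``) is modelled as a resistance R
and compliance C in parallel relating outlet pressure and flow:

    Q = (P - P_out)/R + C d(P - P_out)/dt

Discretized with a backward difference at time step ``dt`` this gives
the update used everywhere in the package:

    P_n = (Q_n R + P_{n-1} C R / dt) / (1 + C R / dt)

(with P measured relative to P_out).  The total resistance is set by the
target mean intracranial pressure and the production rate, and is split
over the outlets in inverse proportion to their outflow fractions; total
compliance is split in direct proportion to the compliance fractions.

The single-node (0D) model lumps all inflow sources into one windkessel
and is used to tune the total compliance so that pressure pulsations
reach a target amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, NamedTuple, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .waveforms import InletSource, combined_0d_inflow

__all__ = [
    "WindkesselOutlet",
    "OutletAllocation",
    "ZeroDModel",
    "ZeroDTrace",
    "ComplianceFit",
    "wk_update",
    "allocate_resistances",
    "allocate_compliances",
    "total_resistance_from_physiology",
    "simulate_0d",
    "pulsation_amplitude",
    "tune_total_compliance",
]


@dataclass(frozen=True)
class WindkesselOutlet:
    """One absorption pathway: resistance and compliance in parallel.

    ``P_state`` is the outlet pressure at the previous accepted time
    step and doubles as the initial condition when a run does not
    override it.  ``C = 0`` degenerates to a pure resistor.
    """

    name: str
    R: float
    C: float = 0.0
    P_out: float = 0.0
    P_state: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"outlet {self.name!r}: R must be > 0")
        if self.C < 0:
            raise ValueError(f"outlet {self.name!r}: C must be >= 0")

    def admittance(self, dt: float) -> float:
        """Discrete admittance dQ/dP of the backward-difference update."""
        return 1.0 / self.R + self.C / dt

    def flow(self, P: float, P_prev: float, dt: float) -> float:
        """Outlet flow (ml/s) at pressure ``P`` given the previous pressure."""
        return (P - self.P_out) / self.R + self.C * (P - P_prev) / dt


@dataclass(frozen=True)
class OutletAllocation:
    """Total resistance/compliance and their distribution over outlets.

    ``q`` maps outlet name to its fraction of the net outflow (must sum
    to 1); ``c`` maps outlet name to its fraction of the total
    compliance (must sum to 1; individual entries may be 0, making that
    outlet a pure resistor).
    """

    R_tot: float
    C_tot: float
    q: Mapping[str, float]
    c: Mapping[str, float]
    ICP_avg: float = 10.0
    Q_production: float = 6.67e-3

    def __post_init__(self) -> None:
        if self.R_tot <= 0:
            raise ValueError("R_tot must be > 0")
        if self.C_tot < 0:
            raise ValueError("C_tot must be >= 0")
        q_sum = float(sum(self.q.values()))
        if abs(q_sum - 1.0) > 1e-9:
            raise ValueError(
                f"outflow fractions must sum to 1, got {q_sum!r} from {dict(self.q)!r}"
            )
        for name, ci in self.c.items():
            if ci < 0:
                raise ValueError(f"compliance fraction for {name!r} must be >= 0")
        c_sum = float(sum(self.c.values()))
        if self.c and abs(c_sum - 1.0) > 1e-9:
            raise ValueError(
                f"compliance fractions must sum to 1, got {c_sum!r} from {dict(self.c)!r}"
            )


def total_resistance_from_physiology(ICP_avg: float, Q_production: float) -> float:
    """Total absorption resistance R_tot = ICP_avg / Q_production.

    At steady state all produced CSF is absorbed, so the mean pressure
    over the parallel outlet resistances equals production times total
    resistance; inverting fixes R_tot (mmHg·s/ml).
    """
    if ICP_avg <= 0 or Q_production <= 0:
        raise ValueError("ICP_avg and Q_production must both be > 0")
    return ICP_avg / Q_production


def allocate_resistances(a: OutletAllocation) -> Dict[str, float]:
    """Per-outlet resistances R_i = R_tot / q_i.

    The parallel combination of the returned resistances equals R_tot
    exactly when the outflow fractions sum to 1.
    """
    for name, qi in a.q.items():
        if qi <= 0:
            raise ValueError(
                f"outflow fraction for {name!r} must be > 0 "
                "(omit the outlet instead of assigning zero flow)"
            )
    return {name: a.R_tot / qi for name, qi in a.q.items()}


def allocate_compliances(a: OutletAllocation) -> Dict[str, float]:
    """Per-outlet compliances C_i = c_i * C_tot (ml/mmHg)."""
    return {name: ci * a.C_tot for name, ci in a.c.items()}


def wk_update(
    P_prev: float,
    Q_n: float,
    R: float,
    C: float,
    dt: float,
    P_out: float = 0.0,
) -> float:
    """Backward-difference windkessel pressure update.

    Returns ``P_out + (Q_n R + (P_prev - P_out) C R / dt) / (1 + C R / dt)``;
    for ``C = 0`` this is exactly the resistor law ``P_out + Q_n R``.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if C < 0:
        raise ValueError("C must be >= 0")
    k = C * R / dt
    return P_out + (Q_n * R + (P_prev - P_out) * k) / (1.0 + k)


@dataclass(frozen=True)
class ZeroDModel:
    """Single-node model: one combined inflow into one windkessel outlet."""

    R_tot: float
    C_tot: float
    inflow: Tuple[InletSource, ...]
    dt: float = 0.05
    P0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.R_tot <= 0:
            raise ValueError("R_tot must be > 0")
        if self.C_tot < 0:
            raise ValueError("C_tot must be >= 0")
        object.__setattr__(self, "inflow", tuple(self.inflow))


class ZeroDTrace(NamedTuple):
    time: np.ndarray
    pressure: np.ndarray


def simulate_0d(m: ZeroDModel, duration: float) -> ZeroDTrace:
    """Integrate the 0D pressure recurrence over ``duration`` seconds.

    The trace starts at ``P0`` and has ``round(duration/dt) + 1``
    samples.  The recurrence is a first-order IIR filter
    ``P_n = b0 Q_n + a1 P_{n-1}`` with ``b0 = R/(1+k)``, ``a1 = k/(1+k)``
    and ``k = C R / dt``, evaluated with :func:`scipy.signal.lfilter`.
    """
    n_steps = int(round(duration / m.dt))
    if n_steps < 1:
        raise ValueError("duration must cover at least one time step")
    t = np.arange(n_steps + 1) * m.dt
    q = np.atleast_1d(combined_0d_inflow(m.inflow, t[1:]))
    k = m.C_tot * m.R_tot / m.dt
    b0 = m.R_tot / (1.0 + k)
    a1 = k / (1.0 + k)
    p_tail, _ = lfilter([b0], [1.0, -a1], q, zi=np.array([a1 * m.P0]))
    return ZeroDTrace(t, np.concatenate(([m.P0], p_tail)))


def pulsation_amplitude(
    time: np.ndarray,
    values: np.ndarray,
    window: Tuple[float, float] | None = None,
) -> float:
    """Half peak-to-peak amplitude ``(max - min)/2`` over a time window.

    ``window`` is an inclusive ``(t0, t1)`` interval; ``None`` uses the
    whole trace.  The window should span at least one full period of the
    slowest active source for the value to be meaningful.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is not None:
        t0, t1 = window
        mask = (time >= t0 - 1e-12) & (time <= t1 + 1e-12)
        values = values[mask]
    if values.size == 0:
        raise ValueError("pulsation_amplitude: window selects no samples")
    return float((values.max() - values.min()) / 2.0)


@dataclass(frozen=True)
class ComplianceFit:
    """Result of the total-compliance grid fit."""

    c_tot: float
    target_amplitude: float
    achieved_amplitude: float
    grid: np.ndarray = field(repr=False)
    amplitudes: np.ndarray = field(repr=False)


def tune_total_compliance(
    inflow: Sequence[InletSource],
    target_amplitude: float = 5.0,
    R_tot: float = 1500.0,
    dt: float = 0.05,
    duration: float = 5.0,
    P0: float = 0.0,
    c_max: float = 1.2,
    n_grid: int = 1000,
) -> ComplianceFit:
    """Fit the total compliance producing a target pressure pulsation.

    Simulates the 0D model from ``P0`` for ``duration`` seconds at each
    of ``n_grid`` compliance values evenly spaced on ``(0, c_max]``
    (zero itself is excluded: a pure resistor has unbounded pulsation
    gain), measures the half peak-to-peak pressure amplitude over the
    full window, and returns the compliance where the amplitude curve
    crosses ``target_amplitude``.  The amplitude is strictly decreasing
    in C, so the crossing is unique; linear interpolation between the
    bracketing grid points refines it beyond the grid spacing.
    """
    if target_amplitude <= 0:
        raise ValueError("target_amplitude must be > 0")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    grid = np.linspace(0.0, c_max, n_grid + 1)[1:]
    amplitudes = np.empty_like(grid)
    for i, c in enumerate(grid):
        trace = simulate_0d(ZeroDModel(R_tot, c, tuple(inflow), dt=dt, P0=P0), duration)
        amplitudes[i] = pulsation_amplitude(trace.time, trace.pressure)
    if not (amplitudes[0] >= target_amplitude >= amplitudes[-1]):
        raise ValueError(
            "target amplitude "
            f"{target_amplitude} mmHg outside achieved range "
            f"[{amplitudes[-1]:.4g}, {amplitudes[0]:.4g}] mmHg on C grid "
            f"(0, {c_max}]"
        )
    # first index where the (decreasing) amplitude falls to/below target
    idx = int(np.argmax(amplitudes <= target_amplitude))
    if amplitudes[idx] == target_amplitude or idx == 0:
        c_fit = float(grid[idx])
        achieved = float(amplitudes[idx])
    else:
        a_hi, a_lo = amplitudes[idx - 1], amplitudes[idx]
        frac = (a_hi - target_amplitude) / (a_hi - a_lo)
        c_fit = float(grid[idx - 1] + frac * (grid[idx] - grid[idx - 1]))
        achieved = float(target_amplitude)
    return ComplianceFit(c_fit, float(target_amplitude), achieved, grid, amplitudes)
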