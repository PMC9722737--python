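"""Rigid multi-compartment hydraulic surrogate of the 3D CSF space.

Compartments are rigid pressure nodes (all storage lives in the outlet
compliances), conduits are linear hydraulic resistances, inlet sources
inject prescribed flows and each windkessel outlet drains its attached
node.  Per time step the model is a small linear system in the node
pressures; it can be solved either monolithically (outlet relations
assembled into the system) or with a partitioned scheme that treats the
flow solve as a black box and couples it implicitly to the outlet
windkessels through a probed linearization — the strategy required when
the flow solver cannot be modified, as with a closed-source 3D code.
The two solvers agree to solver tolerance on any network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import networkx as nx

from .units import PA_PER_MMHG
from .waveforms import InletSource, evaluate_source
from .windkessel import WindkesselOutlet

__all__ = [
    "FluidProperties",
    "WATER",
    "Compartment",
    "Conduit",
    "OutletAttachment",
    "HydraulicNetwork",
    "TimeSeriesResult",
    "ConvergenceError",
    "poiseuille_resistance",
    "reynolds_number",
    "step_monolithic",
    "step_partitioned",
    "run",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid properties in SI units (CSF is water-like)."""

    density: float = 998.2  # kg/m^3
    viscosity: float = 0.001003  # kg/(m s)


WATER = FluidProperties()


class ConvergenceError(RuntimeError):
    """Raised when the partitioned outlet coupling fails to converge."""


def poiseuille_resistance(
    length_mm: float, radius_mm: float, fluid: FluidProperties = WATER
) -> float:
    """Laminar (Poiseuille) resistance of a circular tube, in mmHg·s/ml.

    ``R = 8 mu L / (pi r^4)`` in SI, converted with 1 mmHg = 133.322 Pa
    and 1 ml = 1e-6 m^3.
    """
    if length_mm <= 0 or radius_mm <= 0:
        raise ValueError("length and radius must be > 0")
    length = length_mm * 1e-3
    radius = radius_mm * 1e-3
    r_si = 8.0 * fluid.viscosity * length / (math.pi * radius**4)  # Pa s / m^3
    return r_si * 1e-6 / PA_PER_MMHG


@dataclass(frozen=True)
class Compartment:
    """A rigid fluid zone with a single pressure; no storage of its own."""

    name: str


@dataclass(frozen=True)
class Conduit:
    """A hydraulic connection between two compartments.

    Flow is positive from ``upstream`` to ``downstream`` and obeys
    ``Q = (P_up - P_down) / resistance``.
    """

    name: str
    upstream: str
    downstream: str
    resistance: float
    area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ValueError(f"conduit {self.name!r}: resistance must be > 0")
        if self.area_mm2 is not None and self.area_mm2 <= 0:
            raise ValueError(f"conduit {self.name!r}: area must be > 0")

    @property
    def hydraulic_diameter_mm(self) -> float:
        """Diameter of the equivalent circular cross-section (mm)."""
        if self.area_mm2 is None:
            raise ValueError(f"conduit {self.name!r} has no cross-sectional area")
        return 2.0 * math.sqrt(self.area_mm2 / math.pi)

    @classmethod
    def from_geometry(
        cls,
        name: str,
        upstream: str,
        downstream: str,
        length_mm: float,
        area_mm2: float,
        fluid: FluidProperties = WATER,
    ) -> "Conduit":
        """Build a conduit with Poiseuille resistance from length and area."""
        radius_mm = math.sqrt(area_mm2 / math.pi)
        return cls(
            name,
            upstream,
            downstream,
            poiseuille_resistance(length_mm, radius_mm, fluid),
            area_mm2,
        )


def reynolds_number(
    flow_ml_s: float, conduit: Conduit, fluid: FluidProperties = WATER
) -> float:
    """Reynolds number rho·v·D_h/mu for a conduit carrying ``flow_ml_s``.

    With area in mm^2 and flow in ml/s the mean velocity ``flow/area``
    is directly in m/s.
    """
    if conduit.area_mm2 is None or conduit.area_mm2 <= 0:
        raise ValueError("conduit needs a positive cross-sectional area")
    velocity = abs(flow_ml_s) / conduit.area_mm2  # m/s
    d_h = conduit.hydraulic_diameter_mm * 1e-3
    return fluid.density * velocity * d_h / fluid.viscosity


@dataclass(frozen=True)
class OutletAttachment:
    """A windkessel outlet wired to a compartment."""

    outlet: WindkesselOutlet
    node: str


@dataclass(frozen=True)
class HydraulicNetwork:
    compartments: Tuple[Compartment, ...]
    conduits: Tuple[Conduit, ...]
    sources: Tuple[InletSource, ...]
    outlets: Tuple[OutletAttachment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "conduits", tuple(self.conduits))
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "outlets", tuple(self.outlets))
        self._validate()

    def _validate(self) -> None:
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("compartment names must be unique")
        node_set = set(names)
        for conduit in self.conduits:
            for end in (conduit.upstream, conduit.downstream):
                if end not in node_set:
                    raise ValueError(
                        f"conduit {conduit.name!r} references unknown compartment {end!r}"
                    )
        for source in self.sources:
            if source.node not in node_set:
                raise ValueError(
                    f"source {source.name!r} references unknown compartment {source.node!r}"
                )
        if not self.outlets:
            raise ValueError(
                "network needs at least one outlet (pressure is undefined "
                "under net production otherwise)"
            )
        outlet_names = [a.outlet.name for a in self.outlets]
        if len(set(outlet_names)) != len(outlet_names):
            raise ValueError("outlet names must be unique")
        for attachment in self.outlets:
            if attachment.node not in node_set:
                raise ValueError(
                    f"outlet {attachment.outlet.name!r} references unknown "
                    f"compartment {attachment.node!r}"
                )
        graph = nx.Graph()
        graph.add_nodes_from(node_set)
        graph.add_edges_from((c.upstream, c.downstream) for c in self.conduits)
        if node_set and not nx.is_connected(graph):
            raise ValueError("network topology must be connected")

    @property
    def node_names(self) -> Tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    def conduit(self, name: str) -> Conduit:
        for c in self.conduits:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class TimeSeriesResult:
    """Per-step node pressures (mmHg), conduit and outlet flows (ml/s).

    Rows correspond to the solved steps ``t = dt, 2 dt, ..., duration``;
    the initial condition is not a row.  ``mass_residual`` is the worst
    node imbalance per step; ``iterations`` counts coupling iterations
    (1 for the monolithic solver).
    """

    time: np.ndarray
    node_names: Tuple[str, ...]
    conduit_names: Tuple[str, ...]
    outlet_names: Tuple[str, ...]
    node_pressures: np.ndarray  # (n_steps, n_nodes)
    conduit_flows: np.ndarray  # (n_steps, n_conduits)
    outlet_flows: np.ndarray  # (n_steps, n_outlets)
    outlet_pressures: np.ndarray  # (n_steps, n_outlets)
    mass_residual: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    iterations: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def pressure(self, node: str) -> np.ndarray:
        return self.node_pressures[:, self.node_names.index(node)]

    def conduit_flow(self, conduit: str) -> np.ndarray:
        return self.conduit_flows[:, self.conduit_names.index(conduit)]

    def outlet_flow(self, outlet: str) -> np.ndarray:
        return self.outlet_flows[:, self.outlet_names.index(outlet)]

    def to_frame(self):
        """Canonical tabular form: time, p_<node>, q_<conduit>, qout_<outlet>."""
        import pandas as pd

        data = {"time": self.time}
        for j, name in enumerate(self.node_names):
            data[f"p_{name}"] = self.node_pressures[:, j]
        for j, name in enumerate(self.conduit_names):
            data[f"q_{name}"] = self.conduit_flows[:, j]
        for j, name in enumerate(self.outlet_names):
            data[f"qout_{name}"] = self.outlet_flows[:, j]
        return pd.DataFrame(data)


def _conduit_matrix(net: HydraulicNetwork, index: Mapping[str, int]) -> np.ndarray:
    n = len(index)
    a = np.zeros((n, n))
    for c in net.conduits:
        g = 1.0 / c.resistance
        i, j = index[c.upstream], index[c.downstream]
        a[i, i] += g
        a[i, j] -= g
        a[j, j] += g
        a[j, i] -= g
    return a


def _source_vector(net: HydraulicNetwork, index: Mapping[str, int], t: float) -> np.ndarray:
    b = np.zeros(len(index))
    for s in net.sources:
        b[index[s.node]] += evaluate_source(s, t)
    return b


def _row_from_pressures(
    net: HydraulicNetwork,
    index: Mapping[str, int],
    p: np.ndarray,
    state: Mapping[str, float],
    t: float,
    dt: float,
    iterations: int,
) -> Tuple[dict, Dict[str, float]]:
    conduit_flows = np.array(
        [(p[index[c.upstream]] - p[index[c.downstream]]) / c.resistance for c in net.conduits]
    )
    outlet_flows = np.empty(len(net.outlets))
    outlet_pressures = np.empty(len(net.outlets))
    new_state: Dict[str, float] = {}
    for k, att in enumerate(net.outlets):
        pj = p[index[att.node]]
        outlet_pressures[k] = pj
        outlet_flows[k] = att.outlet.flow(pj, state[att.outlet.name], dt)
        new_state[att.outlet.name] = pj
    # node balance residual: sources + conduit net inflow - outlet outflow
    residual = _source_vector(net, index, t)
    for k, c in enumerate(net.conduits):
        residual[index[c.upstream]] -= conduit_flows[k]
        residual[index[c.downstream]] += conduit_flows[k]
    for k, att in enumerate(net.outlets):
        residual[index[att.node]] -= outlet_flows[k]
    row = {
        "node_pressures": p,
        "conduit_flows": conduit_flows,
        "outlet_flows": outlet_flows,
        "outlet_pressures": outlet_pressures,
        "mass_residual": float(np.max(np.abs(residual))) if residual.size else 0.0,
        "iterations": iterations,
    }
    return row, new_state


def step_monolithic(
    net: HydraulicNetwork,
    state: Mapping[str, float],
    t: float,
    dt: float,
) -> Tuple[dict, Dict[str, float]]:
    """One implicit step with the outlet relations assembled in-system.

    Solves the linear system in node pressures where conduit flows obey
    the resistance law and each outlet flow obeys the discretized
    windkessel relation at its attached node.  Returns the step row and
    the updated outlet pressure state.
    """
    index = {name: i for i, name in enumerate(net.node_names)}
    a = _conduit_matrix(net, index)
    b = _source_vector(net, index, t)
    for att in net.outlets:
        o = att.outlet
        j = index[att.node]
        a[j, j] += o.admittance(dt)
        b[j] += o.P_out / o.R + o.C * state[o.name] / dt
    try:
        p = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular network system: {exc}") from exc
    return _row_from_pressures(net, index, p, state, t, dt, iterations=1)


def _blackbox_flow(
    net: HydraulicNetwork,
    index: Mapping[str, int],
    a_cond: np.ndarray,
    prescribed_nodes: Sequence[int],
    prescribed_p: np.ndarray,
    b_src: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Flow solve with Dirichlet pressures at the outlet-bearing nodes.

    Returns the full node-pressure vector and the net outflow drawn at
    each prescribed node (sources plus conduit inflow).  This is the
    "black box" the partitioned coupling probes: it only knows conduit
    laws and sources, not the outlet models.
    """
    n = len(index)
    free = [i for i in range(n) if i not in set(prescribed_nodes)]
    p = np.zeros(n)
    p[list(prescribed_nodes)] = prescribed_p
    if free:
        a_ff = a_cond[np.ix_(free, free)]
        rhs = b_src[free] - a_cond[np.ix_(free, list(prescribed_nodes))] @ prescribed_p
        try:
            p[free] = np.linalg.solve(a_ff, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular interior flow system: {exc}") from exc
    # net outflow at prescribed node j: F_j = b_j - (A p)_j
    outflow = b_src[list(prescribed_nodes)] - (a_cond @ p)[list(prescribed_nodes)]
    return p, outflow


def step_partitioned(
    net: HydraulicNetwork,
    state: Mapping[str, float],
    t: float,
    dt: float,
    tol: float = 1e-9,
    max_iter: int = 50,
    probe: float = 1e-3,
) -> Tuple[dict, Dict[str, float]]:
    """One step of the partitioned implicit outlet coupling.

    The flow solve (prescribed pressures at outlet-bearing nodes → net
    outlet flows) is treated as a black box.  The first iterate is the
    explicit update: windkessel pressures computed from the flows at the
    previous pressures.  If that is not converged, the flow/pressure
    sensitivity matrix is estimated by probing each outlet node with a
    ``probe`` mmHg perturbation and quasi-Newton updates are iterated
    until successive outlet pressures change by less than ``tol``.
    Outlets sharing a node share its pressure, so the coupling unknowns
    are the outlet-node pressures.
    """
    index = {name: i for i, name in enumerate(net.node_names)}
    a_cond = _conduit_matrix(net, index)
    b_src = _source_vector(net, index, t)

    # group outlets by attachment node, preserving order
    node_order: List[str] = []
    for att in net.outlets:
        if att.node not in node_order:
            node_order.append(att.node)
    node_ids = [index[n] for n in node_order]
    m = len(node_order)
    by_node: Dict[str, List[WindkesselOutlet]] = {n: [] for n in node_order}
    for att in net.outlets:
        by_node[att.node].append(att.outlet)

    # aggregated windkessel relation per node: F_j = g_j P_j - h_j
    g = np.array([sum(o.admittance(dt) for o in by_node[n]) for n in node_order])
    h = np.array(
        [
            sum(o.P_out / o.R + o.C * state[o.name] / dt for o in by_node[n])
            for n in node_order
        ]
    )

    def solve_flow(p_outlets: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return _blackbox_flow(net, index, a_cond, node_ids, p_outlets, b_src)

    p_o = np.array([state[by_node[n][0].name] for n in node_order])
    p_full, f = solve_flow(p_o)
    jac: np.ndarray | None = None
    for niter in range(1, max_iter + 1):
        if niter == 1:
            p_next = (f + h) / g  # explicit windkessel update
        else:
            if jac is None:
                jac = np.empty((m, m))
                for l in range(m):
                    perturbed = p_o.copy()
                    perturbed[l] += probe
                    _, f_pert = solve_flow(perturbed)
                    jac[:, l] = (f_pert - f) / probe
            try:
                dp = np.linalg.solve(np.diag(g) - jac, f - (g * p_o - h))
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular linearized coupling system: {exc}"
                ) from exc
            p_next = p_o + dp
        p_full, f = solve_flow(p_next)
        residual = float(np.max(np.abs((f + h) / g - p_next)))
        p_o = p_next
        if residual < tol or math.isinf(tol):
            break
    else:
        raise ConvergenceError(
            f"outlet coupling did not converge in {max_iter} iterations "
            f"(pressure residual {residual:.3e} mmHg, tol {tol:.3e})"
        )
    return _row_from_pressures(net, index, p_full, state, t, dt, iterations=niter)


InitialPressures = Union[None, float, Mapping[str, float]]


def run(
    net: HydraulicNetwork,
    dt: float = 0.05,
    duration: float = 25.0,
    solver: str = "monolithic",
    initial_pressures: InitialPressures = 0.0,
    tol: float = 1e-9,
    max_iter: int = 50,
    probe: float = 1e-3,
) -> TimeSeriesResult:
    """Sequential time stepping of the network.

    ``initial_pressures`` sets the outlet pressure states at ``t = 0``:
    a scalar applies everywhere, a mapping assigns per outlet name, and
    ``None`` keeps each outlet's own ``P_state``.  The run is fully
    deterministic — identical inputs give bit-identical traces.
    """
    if duration < dt:
        raise ValueError("duration must be >= dt")
    if solver not in ("monolithic", "partitioned"):
        raise ValueError(f"unknown solver {solver!r}")
    n_steps = int(round(duration / dt))
    if initial_pressures is None:
        state = {a.outlet.name: a.outlet.P_state for a in net.outlets}
    elif isinstance(initial_pressures, Mapping):
        state = {a.outlet.name: float(initial_pressures[a.outlet.name]) for a in net.outlets}
    else:
        state = {a.outlet.name: float(initial_pressures) for a in net.outlets}

    n_nodes = len(net.compartments)
    result = TimeSeriesResult(
        time=np.arange(1, n_steps + 1) * dt,
        node_names=net.node_names,
        conduit_names=tuple(c.name for c in net.conduits),
        outlet_names=tuple(a.outlet.name for a in net.outlets),
        node_pressures=np.empty((n_steps, n_nodes)),
        conduit_flows=np.empty((n_steps, len(net.conduits))),
        outlet_flows=np.empty((n_steps, len(net.outlets))),
        outlet_pressures=np.empty((n_steps, len(net.outlets))),
        mass_residual=np.empty(n_steps),
        iterations=np.empty(n_steps, dtype=int),
    )
    for n in range(1, n_steps + 1):
        t = n * dt
        if solver == "monolithic":
            row, state = step_monolithic(net, state, t, dt)
        else:
            row, state = step_partitioned(
                net, state, t, dt, tol=tol, max_iter=max_iter, probe=probe
            )
        i = n - 1
        result.node_pressures[i] = row["node_pressures"]
        result.conduit_flows[i] = row["conduit_flows"]
        result.outlet_flows[i] = row["outlet_flows"]
        result.outlet_pressures[i] = row["outlet_pressures"]
        result.mass_residual[i] = row["mass_residual"]
        result.iterations[i] = row["iterations"]
    return result
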