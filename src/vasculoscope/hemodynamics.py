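"""Steady-state blood flow on vascular graphs.

Each segment obeys a generalized 1D Poiseuille law

    Q_ij = π D_ij⁴ (P_i − P_j) / (128 μ_ij L_ij),

with mass conservation at every junction, the apparent viscosity μ taken
from the empirical in-vivo law (diameter and hematocrit dependent), and
red-cell phase separation at diverging bifurcations.  The coupled
pressure–hematocrit–viscosity fixed point is solved by damped outer
iteration; the nodal pressure system itself is linear and sparse.

Internal units: µm, mmHg, µl/s, cP, s.  Derived per-segment quantities:
velocity u = 4Q/(πD²) (mm/s), wall shear stress τ = 32μQ/(πD³) (dyn/cm²)
and transit time vstt = πD²L/(4Q) (s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .network import NetworkError, VascularNetwork
from .rheology import (
    RheologyParams,
    apparent_viscosity,
    fahraeus_tube_hematocrit,
    phase_separation,
)

__all__ = [
    "FlowConfig",
    "HemodynamicState",
    "ConvergenceError",
    "conductances",
    "solve_pressures",
    "distribute_hematocrit",
    "optimize_boundary_pressures",
    "simulate_hemodynamics",
    "segment_velocity",
    "wall_shear_stress",
    "transit_time",
]

log = logging.getLogger(__name__)

#: mmHg in Pa
MMHG_PA = 133.322387415
#: Poiseuille conductance prefactor giving µl/s per mmHg with D, L in µm, μ in cP
_COND_UNIT = MMHG_PA * 1e-6
#: perfusion floor below which a segment counts as unperfused, µl/s
PERFUSION_FLOOR = 1e-10
#: relative flow floor for the advection digraph: flows below this fraction
#: of the largest flow are solver roundoff (dead-end stubs, balanced loops),
#: not physical perfusion, and carry no red cells or oxygen
ZERO_FLOW_REL = 1e-9


class ConvergenceError(RuntimeError):
    """An iterative solve failed to reach its tolerance."""

    def __init__(self, msg: str, residual: float | None = None, trace=None):
        super().__init__(msg)
        self.residual = residual
        self.trace = trace


@dataclass(frozen=True)
class FlowConfig:
    """Configuration of a hemodynamic simulation.

    Pressure anchors bracket the boundary pressures assigned by the
    optimizer when no measured boundary data exist; ``inlet_hd`` is the
    discharge hematocrit fed into every boundary inflow that carries no
    measured value.
    """

    arterial_pressure: float = 40.0  # mmHg
    venous_pressure: float = 15.0  # mmHg
    inlet_hd: float = 0.45
    pressure_tol: float = 1e-4  # relative, outer loop
    hematocrit_tol: float = 1e-4  # absolute, outer loop
    imbalance_tol: float = 1e-3  # relative global mass imbalance
    max_outer_iterations: int = 200
    relaxation: float = 0.5
    rheology: RheologyParams = field(default_factory=RheologyParams)
    seed: int = 0  # tie-breaking only; solvers are deterministic

    def __post_init__(self):
        if not (0.0 <= self.inlet_hd <= 1.0):
            raise ValueError("inlet_hd must lie in [0, 1]")
        for name in ("pressure_tol", "hematocrit_tol", "imbalance_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.arterial_pressure <= self.venous_pressure:
            raise ValueError("arterial anchor must exceed venous anchor")


@dataclass
class HemodynamicState:
    """Converged per-node and per-segment hemodynamic fields."""

    node_ids: np.ndarray
    segment_ids: np.ndarray
    pressure: np.ndarray  # per node, mmHg
    flow: np.ndarray  # per segment, µl/s, signed node_i→node_j
    hd: np.ndarray  # discharge hematocrit
    ht: np.ndarray  # tube hematocrit
    viscosity: np.ndarray  # cP
    velocity: np.ndarray  # mm/s (magnitude)
    wall_shear_stress: np.ndarray  # dyn/cm² (magnitude)
    transit_time: np.ndarray  # s (+inf on unperfused segments)
    boundary_pressures: dict[int, float]
    iterations: int = 0
    residual: float = 0.0
    zero_flow_segments: np.ndarray | None = None

    @property
    def perfused(self) -> np.ndarray:
        """Mask of perfused segments (|Q| at or above the perfusion floor)."""
        return np.abs(self.flow) >= PERFUSION_FLOOR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": self.segment_ids,
                "flow_ul_s": self.flow,
                "hd": self.hd,
                "ht": self.ht,
                "viscosity_cP": self.viscosity,
                "velocity_mm_s": self.velocity,
                "wss_dyn_cm2": self.wall_shear_stress,
                "vstt_s": self.transit_time,
            }
        )

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "pressure_mmHg": self.pressure})


# -- elementary relations -----------------------------------------------------


def conductances(net: VascularNetwork, viscosity) -> np.ndarray:
    """Per-segment Poiseuille conductance, µl/s per mmHg."""
    mu = np.broadcast_to(np.asarray(viscosity, dtype=float), (net.n_segments,))
    if np.any(mu <= 0):
        raise ValueError("viscosity must be > 0 on every segment")
    return _COND_UNIT * np.pi * net.diameters**4 / (128.0 * mu * net.lengths)


def segment_velocity(diameter, flow):
    """Mean blood velocity magnitude, mm/s (D in µm, Q in µl/s)."""
    return 4.0 * np.abs(flow) * 1e6 / (np.pi * np.asarray(diameter, dtype=float) ** 2)


def wall_shear_stress(diameter, viscosity, flow):
    """Wall shear stress magnitude, dyn/cm² (D µm, μ cP, Q µl/s)."""
    d = np.asarray(diameter, dtype=float)
    return 32.0 * np.asarray(viscosity, float) * np.abs(flow) * 1e7 / (np.pi * d**3)


def transit_time(diameter, length, flow):
    """Segment transit time vstt = vessel volume / flow, s (+inf at Q = 0)."""
    d = np.asarray(diameter, dtype=float)
    q = np.abs(np.asarray(flow, dtype=float))
    vol = np.pi * d**2 * np.asarray(length, float) * 1e-9 / 4.0  # µl
    with np.errstate(divide="ignore"):
        return np.where(q > 0, vol / np.where(q > 0, q, 1.0), np.inf)


# -- pressure solve -----------------------------------------------------------


def solve_pressures(
    net: VascularNetwork,
    boundary_pressures: dict[int, float],
    viscosity,
    boundary_flows: dict[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the nodal pressure system and return (P per node, Q per segment).

    Dirichlet conditions fix the pressure (mmHg) at the listed nodes;
    optional Neumann conditions inject a signed flow (µl/s, inflow
    positive) at boundary nodes.  Every connected component must contain at
    least one pressure node, otherwise the system is singular and a
    :class:`NetworkError` names the offending component.
    """
    n = net.n_nodes
    e = net.endpoint_indices
    g = conductances(net, viscosity)
    boundary_flows = boundary_flows or {}

    fixed_idx = np.array([net.node_index(i) for i in boundary_pressures], dtype=np.int64)
    fixed_val = np.array([boundary_pressures[i] for i in boundary_pressures], dtype=float)

    adj = sp.coo_matrix((np.ones(net.n_segments), (e[:, 0], e[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    has_fixed = np.zeros(n_comp, dtype=bool)
    has_fixed[labels[fixed_idx]] = True
    if not np.all(has_fixed):
        bad = int(np.flatnonzero(~has_fixed)[0])
        members = net.node_ids[labels == bad]
        raise NetworkError(
            f"component {bad} (nodes {members[:10].tolist()}...) has no boundary pressure; "
            "the pressure system is singular"
        )

    # weighted graph Laplacian
    rows = np.concatenate([e[:, 0], e[:, 1], e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0], e[:, 0], e[:, 1]])
    vals = np.concatenate([-g, -g, g, g])
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    rhs = np.zeros(n)
    for nid, q in boundary_flows.items():
        rhs[net.node_index(nid)] += q

    free = np.setdiff1d(np.arange(n), fixed_idx, assume_unique=False)
    p = np.zeros(n)
    p[fixed_idx] = fixed_val
    if len(free):
        a_ff = lap[free][:, free].tocsc()
        b = rhs[free] - lap[free][:, fixed_idx] @ fixed_val
        p[free] = spla.spsolve(a_ff, b)
    q = g * (p[e[:, 0]] - p[e[:, 1]])
    return p, q


def interior_mass_residual(net: VascularNetwork, flow, boundary_flow_nodes=()) -> float:
    """Largest |ΣQ| over interior nodes, µl/s (conservation check)."""
    div = np.zeros(net.n_nodes)
    e = net.endpoint_indices
    np.add.at(div, e[:, 0], -flow)
    np.add.at(div, e[:, 1], flow)
    interior = net.degrees > 1
    for nid in boundary_flow_nodes:
        interior[net.node_index(nid)] = False
    return float(np.max(np.abs(div[interior]))) if interior.any() else 0.0


# -- hematocrit distribution --------------------------------------------------


def distribute_hematocrit(
    net: VascularNetwork,
    flow: np.ndarray,
    inlet_hd: float,
    params: RheologyParams = RheologyParams(),
    boundary_hd: dict[int, float] | None = None,
) -> np.ndarray:
    """Propagate discharge hematocrit through the flow digraph.

    Nodes are processed in topological order of the flow direction (the
    steady-flow digraph is acyclic because pressure strictly decreases
    along flowing segments).  At each node the inflowing red-cell flux is
    mixed; a single outflow inherits the mixed hematocrit, while diverging
    branches split red-cell flux by the empirical phase-separation law,
    applied recursively over flow-ranked daughter pairs for junctions with
    more than two outflows.  Zero-flow segments receive H_D = 0.

    ``boundary_hd`` overrides the default ``inlet_hd`` at specific boundary
    inflow nodes (measured data).
    """
    m = net.n_segments
    e = net.endpoint_indices
    boundary_hd = boundary_hd or {}
    hd = np.zeros(m)
    # relative floor keeps numerically-zero flows (dead-end stubs) out of
    # the digraph; their red-cell flux contribution is below any tolerance
    qmax = float(np.max(np.abs(flow))) if m else 0.0
    flowing = np.abs(flow) > ZERO_FLOW_REL * qmax

    # upstream/downstream node index per flowing segment
    up = np.where(flow >= 0, e[:, 0], e[:, 1])
    down = np.where(flow >= 0, e[:, 1], e[:, 0])

    out_segs: list[list[int]] = [[] for _ in range(net.n_nodes)]
    in_segs: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for s in np.flatnonzero(flowing):
        out_segs[up[s]].append(int(s))
        in_segs[down[s]].append(int(s))
    # deterministic ordering: by segment id
    for lst in (*out_segs, *in_segs):
        lst.sort(key=lambda s: int(net.segment_ids[s]))

    # Kahn topological order over nodes touched by flow
    indeg = np.array([len(lst) for lst in in_segs])
    queue = [v for v in range(net.n_nodes) if indeg[v] == 0 and out_segs[v]]
    order = []
    indeg_w = indeg.copy()
    while queue:
        v = queue.pop(0)
        order.append(v)
        for s in out_segs[v]:
            w = down[s]
            indeg_w[w] -= 1
            if indeg_w[w] == 0:
                queue.append(int(w))
    n_active = sum(1 for v in range(net.n_nodes) if out_segs[v] or in_segs[v])
    if len([v for v in order if out_segs[v] or in_segs[v]]) < n_active:
        # residual cycle (only possible with degenerate equal pressures):
        # relax iteratively from the partial order
        order = [v for v in range(net.n_nodes) if out_segs[v] or in_segs[v]]
        return _relax_hematocrit(net, flow, inlet_hd, params, boundary_hd, order, up, down,
                                 in_segs, out_segs)

    absq = np.abs(flow)
    for v in order:
        if not out_segs[v]:
            continue
        if in_segs[v]:
            q_in = absq[in_segs[v]]
            rbc_in = float(np.sum(q_in * hd[in_segs[v]]))
            blood_in = float(np.sum(q_in))
            d_feed = float(np.sum(q_in * net.diameters[in_segs[v]]) / blood_in)
        else:  # boundary inflow node
            blood_in = float(np.sum(absq[out_segs[v]]))
            h0 = boundary_hd.get(int(net.node_ids[v]), inlet_hd)
            rbc_in = blood_in * h0
            d_feed = float(net.diameters[out_segs[v][0]])
        _split_rbc(net, v, out_segs[v], absq, rbc_in, blood_in, d_feed, hd, params)
    return hd


def _split_rbc(net, v, daughters, absq, rbc, blood, d_feed, hd, params):
    """Assign daughter H_D values, conserving red-cell flux exactly."""
    if blood <= 0 or not daughters:
        return
    rbc = max(rbc, 0.0)  # guard against roundoff residue of the recursion
    if len(daughters) == 1:
        s = daughters[0]
        hd[s] = min(rbc / absq[s], 1.0) if absq[s] > 0 else 0.0
        return
    h_feed = rbc / blood
    ranked = sorted(daughters, key=lambda s: (-absq[s], int(net.segment_ids[s])))
    alpha, rest = ranked[0], ranked[1:]
    q_alpha = float(absq[alpha])
    q_rest = float(np.sum(absq[rest]))
    d_rest = float(np.sqrt(np.mean(net.diameters[rest] ** 2)))
    fq_b = q_alpha / (q_alpha + q_rest) if (q_alpha + q_rest) > 0 else 0.0
    fq_e = phase_separation(fq_b, d_feed, float(net.diameters[alpha]), d_rest,
                            min(h_feed, 1.0), params)
    rbc_alpha = fq_e * rbc
    hd[alpha] = min(rbc_alpha / q_alpha, 1.0) if q_alpha > 0 else 0.0
    rbc_alpha = hd[alpha] * q_alpha  # after clamping, remainder stays conserved
    _split_rbc(net, v, rest, absq, rbc - rbc_alpha, q_rest, d_feed, hd, params)


def _relax_hematocrit(net, flow, inlet_hd, params, boundary_hd, order, up, down,
                      in_segs, out_segs, max_iter=500, tol=1e-12):
    """Fallback fixed-point sweep for degenerate (cyclic) flow digraphs."""
    absq = np.abs(flow)
    hd = np.full(net.n_segments, inlet_hd)
    hd[absq == 0] = 0.0
    for it in range(max_iter):
        prev = hd.copy()
        for v in order:
            if not out_segs[v]:
                continue
            if in_segs[v]:
                q_in = absq[in_segs[v]]
                blood = float(np.sum(q_in))
                rbc = float(np.sum(q_in * hd[in_segs[v]]))
                d_feed = float(np.sum(q_in * net.diameters[in_segs[v]]) / blood) if blood else 0.0
            else:
                blood = float(np.sum(absq[out_segs[v]]))
                rbc = blood * boundary_hd.get(int(net.node_ids[v]), inlet_hd)
                d_feed = float(net.diameters[out_segs[v][0]])
            _split_rbc(net, v, out_segs[v], absq, rbc, blood, d_feed, hd, params)
        if np.max(np.abs(hd - prev)) < tol:
            return hd
    raise ConvergenceError(
        "hematocrit relaxation did not converge",
        residual=float(np.max(np.abs(hd - prev))),
    )


# -- boundary pressure optimization -------------------------------------------


def optimize_boundary_pressures(net: VascularNetwork, config: FlowConfig) -> dict[int, float]:
    """Assign boundary pressures ensuring global mass conservation.

    If every boundary node already carries a pressure condition those are
    returned unchanged (optimization bypassed).  Otherwise candidate
    feeders and drainers are ranked by the diameter of their attached
    segment and pressures are initialized by linear interpolation in
    log-diameter between the venous and arterial anchors — larger-bore
    boundary vessels feed, smaller ones drain.  Damped corrections shrink
    any residual global imbalance; with pure-pressure boundaries the nodal
    solve conserves mass to solver precision, so the loop normally
    terminates at the first check.
    """
    bids = net.boundary_node_ids
    if len(bids) < 2:
        raise NetworkError("boundary pressure optimization needs >= 2 boundary nodes")
    given = {
        int(nid): bc.pressure
        for nid, bc in net.boundary_conditions.items()
        if bc.kind == "pressure"
    }
    if all(int(b) in given for b in bids):
        return {int(b): float(given[int(b)]) for b in bids}

    # diameter of the single segment attached to each boundary node
    e = net.endpoint_indices
    d_at = {}
    for s in range(net.n_segments):
        for side in (0, 1):
            nid = int(net.node_ids[e[s, side]])
            d_at.setdefault(nid, float(net.diameters[s]))
    logd = np.array([np.log(d_at[int(b)]) for b in bids])
    lo, hi = float(logd.min()), float(logd.max())
    if hi > lo:
        frac = (logd - lo) / (hi - lo)
    else:
        # tied diameters: fall back to rank order (by node id) so that at
        # least one feeder/drainer pair exists and flow is nonzero
        order = np.argsort([int(b) for b in bids])
        frac = np.empty(len(bids))
        frac[order] = np.linspace(0.0, 1.0, len(bids))
    pressures = {
        int(b): float(config.venous_pressure + frac[k] * (config.arterial_pressure - config.venous_pressure))
        for k, b in enumerate(bids)
    }
    pressures.update({k: float(v) for k, v in given.items()})

    mu = apparent_viscosity(net.diameters, np.full(net.n_segments, config.inlet_hd),
                            config.rheology)
    last = np.inf
    for it in range(config.max_outer_iterations):
        imb = _global_imbalance(net, pressures, mu)
        last = imb
        if imb < config.imbalance_tol:
            return pressures
        # damped shrink of pressure deviations toward the midpoint
        mid = 0.5 * (config.arterial_pressure + config.venous_pressure)
        for b in pressures:
            if b not in given:
                pressures[b] = mid + (1.0 - config.relaxation * imb) * (pressures[b] - mid)
    raise ConvergenceError(
        f"boundary-pressure optimization: imbalance {last:.3e} after "
        f"{config.max_outer_iterations} iterations",
        residual=last,
    )


def _global_imbalance(net, pressures, mu) -> float:
    _, q = solve_pressures(net, pressures, mu)
    e = net.endpoint_indices
    bset = {net.node_index(b) for b in pressures}
    inflow = outflow = 0.0
    for s in range(net.n_segments):
        for side, sign in ((0, 1.0), (1, -1.0)):
            if e[s, side] in bset:
                qb = sign * q[s]  # into the network
                if qb > 0:
                    inflow += qb
                else:
                    outflow -= qb
    if inflow <= 0:
        return np.inf
    return abs(inflow - outflow) / inflow


# -- outer fixed point --------------------------------------------------------


def simulate_hemodynamics(net: VascularNetwork, config: FlowConfig = FlowConfig()) -> HemodynamicState:
    """Run the coupled pressure–viscosity–hematocrit fixed point.

    The outer loop alternates: apparent viscosity from current H_D →
    nodal pressure solve → phase-separated hematocrit from the new flow
    field, with under-relaxation on H_D, until the largest relative
    pressure change and absolute H_D change both fall below tolerance.
    """
    boundary_pressures = optimize_boundary_pressures(net, config)
    boundary_flows = {
        int(nid): bc.flow
        for nid, bc in net.boundary_conditions.items()
        if bc.kind in ("flow", "flow_hd")
    }
    boundary_hd = {
        int(nid): bc.hd
        for nid, bc in net.boundary_conditions.items()
        if bc.kind == "flow_hd" and bc.hd is not None
    }
    # nodes with flow conditions must not also get optimizer pressures
    for nid in boundary_flows:
        boundary_pressures.pop(nid, None)
    if not boundary_pressures:
        raise NetworkError("at least one pressure boundary condition is required")

    hd = np.full(net.n_segments, config.inlet_hd)
    p_prev = None
    flow = np.zeros(net.n_segments)
    mu = np.full(net.n_segments, config.rheology.plasma_viscosity)
    for it in range(1, config.max_outer_iterations + 1):
        mu = apparent_viscosity(net.diameters, np.clip(hd, 0.0, 0.99), config.rheology)
        p, flow = solve_pressures(net, boundary_pressures, mu, boundary_flows)
        hd_new = distribute_hematocrit(net, flow, config.inlet_hd, config.rheology, boundary_hd)
        # convergence is judged on perfused segments: unperfused ones carry
        # H_D = 0 by definition and their roundoff-level flows may flip sign
        perf = np.abs(flow) >= PERFUSION_FLOOR
        if not perf.any():
            perf = np.ones(net.n_segments, dtype=bool)
        dh = float(np.max(np.abs(hd_new[perf] - hd[perf]))) if net.n_segments else 0.0
        dp = (
            float(np.max(np.abs(p - p_prev)) / max(np.max(np.abs(p)), 1e-300))
            if p_prev is not None
            else np.inf
        )
        converged = dh < config.hematocrit_tol and dp < config.pressure_tol
        hd = hd + config.relaxation * (hd_new - hd)
        p_prev = p
        if converged:
            break
    else:
        raise ConvergenceError(
            f"hemodynamic outer loop did not converge in {config.max_outer_iterations} "
            f"iterations (dH = {dh:.2e}, dP = {dp:.2e})",
            residual=max(dh, dp),
        )

    # final consistent triple: μ(H_D) → (P, Q) → H_D(Q); the last hematocrit
    # pass makes red-cell flux conservation exact on the reported flow field
    mu = apparent_viscosity(net.diameters, np.clip(hd, 0.0, 0.99), config.rheology)
    p, flow = solve_pressures(net, boundary_pressures, mu, boundary_flows)
    hd = distribute_hematocrit(net, flow, config.inlet_hd, config.rheology, boundary_hd)
    ht = fahraeus_tube_hematocrit(net.diameters, hd, config.rheology)
    state = HemodynamicState(
        node_ids=net.node_ids.copy(),
        segment_ids=net.segment_ids.copy(),
        pressure=p,
        flow=flow,
        hd=hd,
        ht=np.asarray(ht, dtype=float).reshape(net.n_segments),
        viscosity=np.asarray(mu, dtype=float).reshape(net.n_segments),
        velocity=segment_velocity(net.diameters, flow),
        wall_shear_stress=wall_shear_stress(net.diameters, mu, flow),
        transit_time=transit_time(net.diameters, net.lengths, flow),
        boundary_pressures=boundary_pressures,
        iterations=it,
        residual=float(max(dh, 0.0)),
        zero_flow_segments=net.segment_ids[np.abs(flow) == 0.0],
    )
    log.info("hemodynamics converged in %d outer iterations (dH=%.2e)", it, dh)
    return state
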