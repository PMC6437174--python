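"""Intravascular oxygen transport on a converged flow field.

Blood carries oxygen dissolved in plasma and red cells (solubility α_b, a
hematocrit-weighted blend of the red-cell and plasma solubilities) and
bound to hemoglobin (Hill saturation S_Hb with exponent n_hill and
half-saturation pressure P_50).  Along each vessel segment the advected
oxygen content drops by the wall efflux J_wall:

    Q_b (α_b ΔP + H_D C_bind ΔS_Hb) = J_wall

The tissue is partitioned into domains proportional to segment length, so
J_wall is the tissue oxygen demand M_c·m_tissue shared among segments by
length.  Only segments that transport significant oxygen take wall flux:
eligibility requires discharge hematocrit H_D > 0.01 and transit time
vstt < 25 s.  Extravascular diffusion is out of scope: the model reports
intravascular oxygenation only.

Given the saturation values the nodal oxygen-tension system is linear
and, because steady flow defines an acyclic digraph, lower-triangular in
topological order; each node's balance is solved exactly (saturation
implicit) by a forward sweep, and a second sweep certifies convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hemodynamics import ZERO_FLOW_REL, ConvergenceError, HemodynamicState
from .network import VascularNetwork

__all__ = [
    "OxygenParams",
    "OxygenState",
    "hill_saturation",
    "blood_solubility",
    "wall_fluxes",
    "solve_oxygen",
]

log = logging.getLogger(__name__)

#: µl/s → ml/s
_UL_TO_ML = 1e-3


@dataclass(frozen=True)
class OxygenParams:
    """Physiological constants and solver settings for oxygen transport.

    ``m_c`` (tissue oxygen consumption, ml O2 g⁻¹ s⁻¹) has no default: it
    is tumor-line specific and must be supplied.  Hill constants and the
    plasma solubility default to hemoglobin/plasma standards (n = 2.7,
    P_50 = 37 mmHg, α_pl = 2.82×10⁻⁵ ml O2 ml⁻¹ mmHg⁻¹); the red-cell
    solubility and hemoglobin binding capacity default to standard
    physiological values (see docs/methods.md).
    """

    m_c: float  # ml O2 · g⁻¹ · s⁻¹
    m_tissue: float | None = None  # g; if None, tissue_density × tumor volume
    tissue_density: float = 1.0  # g/ml
    c_bind: float = 0.5  # ml O2 / ml RBC
    n_hill: float = 2.7
    p50: float = 37.0  # mmHg
    alpha_pl: float = 2.82e-5  # ml O2 · ml⁻¹ · mmHg⁻¹
    alpha_rbc: float = 3.38e-5  # ml O2 · ml⁻¹ · mmHg⁻¹
    hd_threshold: float = 0.01  # eligibility: H_D must exceed this
    vstt_threshold: float = 25.0  # s; eligibility: transit time below this
    inlet_po2: float = 50.0  # mmHg at boundary inflows
    tolerance: float = 1e-9  # mmHg, max tension change between iterations
    max_iterations: int = 500
    normalize_eligible_only: bool = True  # ΣL over eligible vs all segments

    def __post_init__(self):
        for name in ("m_c", "n_hill", "p50", "alpha_pl", "alpha_rbc",
                     "tolerance", "vstt_threshold", "tissue_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.c_bind < 0 or self.hd_threshold < 0:
            raise ValueError("c_bind and hd_threshold must be >= 0")

    def tissue_mass(self, net: VascularNetwork) -> float:
        """Tissue mass in g, from m_tissue or density × tumor volume."""
        if self.m_tissue is not None:
            return self.m_tissue
        if net.tumor_volume_mm3 is None:
            raise ValueError("need m_tissue or net.tumor_volume_mm3 to set tissue mass")
        return self.tissue_density * net.tumor_volume_mm3 * 1e-3  # mm³ → ml


@dataclass
class OxygenState:
    """Converged intravascular oxygen fields."""

    node_ids: np.ndarray
    segment_ids: np.ndarray
    node_po2: np.ndarray  # mmHg per node (0 on unreached nodes)
    segment_po2: np.ndarray  # mmHg, mean of endpoint tensions
    saturation: np.ndarray  # S_Hb at segment mean PO2
    solubility: np.ndarray  # α_b per segment
    wall_flux: np.ndarray  # ml O2/s per segment (0 if ineligible)
    eligible: np.ndarray  # bool per segment
    iterations: int = 0
    residual: float = 0.0
    #: total demand that could not be extracted on anoxic (clamped) branches,
    #: ml O2/s; zero when supply covers demand everywhere, in which case
    #: inlet − outlet advected O2 equals ΣJ_wall exactly
    unmet_demand: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": self.segment_ids,
                "po2_mmHg": self.segment_po2,
                "s_hb": self.saturation,
                "alpha_b": self.solubility,
                "j_wall_mlO2_s": self.wall_flux,
                "eligible": self.eligible,
            }
        )


def hill_saturation(po2, params: OxygenParams | None = None, *, n_hill=None, p50=None):
    """Hemoglobin oxygen saturation S = P^n / (P^n + P50^n).

    Strictly increasing in P; S(P_50) = 1/2 by definition.
    """
    n = n_hill if n_hill is not None else (params.n_hill if params else 2.7)
    p_half = p50 if p50 is not None else (params.p50 if params else 37.0)
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("oxygen tension must be >= 0")
    pn = p**n
    out = pn / (pn + p_half**n)
    return out if out.shape else float(out)


def blood_solubility(ht, params: OxygenParams | None = None, *, alpha_rbc=None, alpha_pl=None):
    """Effective blood oxygen solubility α_b = H_T α_RBC + (1−H_T) α_pl."""
    a_rbc = alpha_rbc if alpha_rbc is not None else (params.alpha_rbc if params else 3.38e-5)
    a_pl = alpha_pl if alpha_pl is not None else (params.alpha_pl if params else 2.82e-5)
    h = np.asarray(ht, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("tube hematocrit must lie in [0, 1]")
    out = h * a_rbc + (1.0 - h) * a_pl
    return out if out.shape else float(out)


def wall_fluxes(
    net: VascularNetwork,
    hemo: HemodynamicState,
    params: OxygenParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment wall oxygen efflux and eligibility flags.

    A segment is eligible iff H_D > ``hd_threshold`` and vstt <
    ``vstt_threshold``.  Eligible segments share the total tissue demand
    M_c·m_tissue in proportion to their length; ineligible segments take
    zero flux.  By default lengths are normalized over eligible segments
    only, so the delivered total equals the demand exactly (set
    ``normalize_eligible_only=False`` to normalize over all segments).
    """
    eligible = (hemo.hd > params.hd_threshold) & (hemo.transit_time < params.vstt_threshold)
    if not np.any(eligible):
        raise ValueError("no eligible segment: oxygen demand unservable")
    total = params.m_c * params.tissue_mass(net)
    denom = float(np.sum(net.lengths[eligible])) if params.normalize_eligible_only else float(
        np.sum(net.lengths)
    )
    j = np.where(eligible, total * net.lengths / denom, 0.0)
    return j, eligible


def _solve_node_tension(a_out: float, b_out: float, rhs: float, params: OxygenParams) -> float:
    """Solve a·P + b·S_Hb(P) = rhs for P ≥ 0 (monotone; unique root)."""
    if a_out <= 0.0:
        return 0.0
    if b_out == 0.0:
        return rhs / a_out
    from scipy.optimize import brentq

    hi = rhs / a_out  # f(hi) = b·S(hi) ≥ 0, f(0) = −rhs < 0

    def f(p):
        return a_out * p + b_out * float(hill_saturation(p, params)) - rhs

    if f(hi) <= 0.0:  # numerical guard; S ≥ 0 makes this impossible analytically
        return hi
    return float(brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16))


def solve_oxygen(
    net: VascularNetwork,
    hemo: HemodynamicState,
    params: OxygenParams,
    boundary_po2: dict[int, float] | None = None,
) -> OxygenState:
    """Solve nodal oxygen tensions by Hill fixed-point iteration.

    Enforces the upwind nodal balance — for each node reached by flow,
    advected oxygen in (dissolved + hemoglobin-bound, minus wall losses of
    the feeding segments) equals advected oxygen out.  Sweeping nodes in
    topological order of the flow digraph makes the system triangular;
    each node reduces to one monotone scalar equation in its tension,
    solved with the Hill saturation implicit.  Sweeps repeat until the
    largest tension change falls below tolerance (the second sweep
    certifies the fixed point).  Boundary inflow nodes are fixed at
    ``params.inlet_po2`` unless overridden via ``boundary_po2``.

    Negative tensions appearing during iteration are clamped to zero with
    a warning (oxygen demand exceeding supply on a branch).
    """
    m = net.n_segments
    e = net.endpoint_indices
    flow_ml = hemo.flow * _UL_TO_ML
    absq = np.abs(flow_ml)
    qmax = float(np.max(absq)) if m else 0.0
    flowing = absq > ZERO_FLOW_REL * qmax
    boundary_po2 = boundary_po2 or {}

    j_wall, eligible = wall_fluxes(net, hemo, params)
    alpha = np.asarray(blood_solubility(hemo.ht, params), dtype=float).reshape(m)

    up = np.where(hemo.flow >= 0, e[:, 0], e[:, 1])
    down = np.where(hemo.flow >= 0, e[:, 1], e[:, 0])

    in_segs: list[list[int]] = [[] for _ in range(net.n_nodes)]
    out_segs: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for s in np.flatnonzero(flowing):
        out_segs[up[s]].append(int(s))
        in_segs[down[s]].append(int(s))

    touched = np.array([bool(in_segs[v] or out_segs[v]) for v in range(net.n_nodes)])
    inflow_boundary = np.array(
        [bool(out_segs[v]) and not in_segs[v] for v in range(net.n_nodes)]
    )
    fixed = inflow_boundary
    unknown = touched & ~fixed

    p_nodes = np.zeros(net.n_nodes)
    for v in np.flatnonzero(fixed):
        p_nodes[v] = boundary_po2.get(int(net.node_ids[v]), params.inlet_po2)

    # Kahn topological order: the steady flow digraph is acyclic because
    # pressure strictly decreases along flowing segments, so the upwind
    # nodal system is lower-triangular in this order
    indeg = np.array([len(lst) for lst in in_segs])
    queue = [v for v in range(net.n_nodes) if indeg[v] == 0 and touched[v]]
    order = []
    indeg_w = indeg.copy()
    while queue:
        v = queue.pop(0)
        order.append(v)
        for s in out_segs[v]:
            w = int(down[s])
            indeg_w[w] -= 1
            if indeg_w[w] == 0:
                queue.append(w)
    if len(order) < int(np.sum(touched)):
        raise ConvergenceError(
            "flow digraph contains a cycle; oxygen advection order undefined",
            residual=np.inf,
        )

    cb = params.c_bind
    clamp_warned = False
    it = 0
    resid = np.inf
    # fixed-point on the saturation field: sweep the DAG solving each
    # node's monotone scalar balance a·P + b·S_Hb(P) = advected-in with
    # S implicit per node; the forward sweep is exact, so the second
    # sweep certifies the fixed point (ΔP below tolerance)
    unmet = 0.0
    for it in range(1, params.max_iterations + 1):
        p_prev = p_nodes.copy()
        unmet = 0.0
        for v in order:
            if not unknown[v]:
                continue
            rhs = 0.0
            for s in in_segs[v]:
                u = int(up[s])
                pu = max(p_nodes[u], 0.0)
                rhs += absq[s] * (
                    alpha[s] * p_nodes[u]
                    + hemo.hd[s] * cb * float(hill_saturation(pu, params))
                ) - j_wall[s]
            out_list = out_segs[v] if out_segs[v] else in_segs[v]
            a_out = float(np.sum(absq[out_list] * alpha[out_list]))
            b_out = float(np.sum(absq[out_list] * hemo.hd[out_list])) * cb
            if rhs <= 0.0:
                if not clamp_warned:
                    warnings.warn(
                        "negative oxygen tensions clamped to 0 (demand exceeds "
                        "supply on some branches)",
                        stacklevel=2,
                    )
                    clamp_warned = True
                p_nodes[v] = 0.0
                unmet += -rhs
                continue
            p_nodes[v] = _solve_node_tension(a_out, b_out, rhs, params)
        resid = float(np.max(np.abs(p_nodes - p_prev))) if unknown.any() else 0.0
        if resid < params.tolerance:
            break
    else:
        raise ConvergenceError(
            f"oxygen fixed point did not converge in {params.max_iterations} iterations",
            residual=resid,
        )

    seg_po2 = np.zeros(m)
    for s in range(m):
        if flowing[s]:
            seg_po2[s] = 0.5 * (p_nodes[up[s]] + p_nodes[down[s]])
    sat = np.asarray(hill_saturation(seg_po2, params), dtype=float).reshape(m)
    log.info("oxygen transport converged in %d iterations (resid %.2e mmHg)", it, resid)
    return OxygenState(
        node_ids=net.node_ids.copy(),
        segment_ids=net.segment_ids.copy(),
        node_po2=p_nodes,
        segment_po2=seg_po2,
        saturation=sat,
        solubility=alpha,
        wall_flux=j_wall,
        eligible=eligible,
        iterations=it,
        residual=resid,
        unmet_demand=unmet,
    )


def advected_o2_balance(
    net: VascularNetwork,
    hemo: HemodynamicState,
    oxy: OxygenState,
    params: OxygenParams,
) -> tuple[float, float, float]:
    """(inlet advected O2, outlet advected O2, ΣJ_wall), all ml O2/s.

    At convergence inlet − outlet equals the total wall efflux.
    """
    e = net.endpoint_indices
    flow_ml = hemo.flow * _UL_TO_ML
    absq = np.abs(flow_ml)
    up = np.where(hemo.flow >= 0, e[:, 0], e[:, 1])
    down = np.where(hemo.flow >= 0, e[:, 1], e[:, 0])
    deg = net.degrees
    qmax = float(np.max(absq)) if net.n_segments else 0.0
    inlet = outlet = 0.0
    for s in range(net.n_segments):
        if absq[s] <= ZERO_FLOW_REL * qmax:
            continue
        content_up = oxy.solubility[s] * oxy.node_po2[up[s]] + hemo.hd[s] * params.c_bind * float(
            hill_saturation(max(oxy.node_po2[up[s]], 0.0), params)
        )
        content_dn = oxy.solubility[s] * oxy.node_po2[down[s]] + hemo.hd[s] * params.c_bind * float(
            hill_saturation(max(oxy.node_po2[down[s]], 0.0), params)
        )
        if deg[up[s]] == 1:
            inlet += absq[s] * content_up
        if deg[down[s]] == 1:
            outlet += absq[s] * content_dn
    return inlet, outlet, float(np.sum(oxy.wall_flux))
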