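"""Seeded generators of vascular networks for simulation and testing.

Fully determined validation topologies (a straight vessel chain, a
symmetric bifurcation tree, a rectangular lattice) plus a tumor-like
random generator that emulates the salient statistics of tumor
microvasculature: a densely vascularized rim around a sparser core,
positively skewed (log-normal) diameters, loopy topology, boundary nodes
on the tumor surface.  All generators are deterministic for a given seed
and produce networks that pass structural validation with zero errors.

A loader for the published 546-segment rat mesentery network (external
dataset, not bundled) reads a documented two-file text layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from .network import BoundaryCondition, NetworkError, Node, Segment, VascularNetwork

__all__ = [
    "TumorLikeParams",
    "make_line",
    "make_bifurcation_tree",
    "make_lattice",
    "make_tumor_like",
    "load_mesentery",
]


def make_line(
    diameter: float = 10.0,
    segment_length: float = 100.0,
    n_segments: int = 1,
    inlet_pressure: float | None = None,
    outlet_pressure: float | None = None,
) -> VascularNetwork:
    """A straight chain of ``n_segments`` along x; 2 boundary nodes."""
    if diameter <= 0 or segment_length <= 0 or n_segments < 1:
        raise ValueError("diameter, segment_length and n_segments must be positive")
    nodes = [
        Node(i, (i * segment_length, 0.0, 0.0)) for i in range(n_segments + 1)
    ]
    segments = [
        Segment(i, i, i + 1, diameter, segment_length) for i in range(n_segments)
    ]
    bcs = []
    if inlet_pressure is not None:
        bcs.append(BoundaryCondition(0, "pressure", pressure=inlet_pressure))
    if outlet_pressure is not None:
        bcs.append(BoundaryCondition(n_segments, "pressure", pressure=outlet_pressure))
    return VascularNetwork(nodes, segments, bcs)


def make_bifurcation_tree(
    depth: int = 3,
    root_diameter: float = 40.0,
    diameter_ratio: float = 0.79,
    segment_length: float = 100.0,
    root_pressure: float | None = None,
    leaf_pressure: float | None = None,
) -> VascularNetwork:
    """A perfect binary tree: root segment then ``depth`` generations of
    symmetric bifurcations; the root node and the 2^depth leaves are the
    boundary.  Daughter diameters shrink by ``diameter_ratio`` per
    generation (≈2^(−1/3) ≈ 0.79 mimics volume-preserving branching).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    nodes = [Node(0, (0.0, 0.0, 0.0)), Node(1, (segment_length, 0.0, 0.0))]
    segments = [Segment(0, 0, 1, root_diameter, segment_length)]
    frontier = [1]  # node ids of current generation tips
    next_node = 2
    next_seg = 1
    for level in range(1, depth + 1):
        d = root_diameter * diameter_ratio**level
        new_frontier = []
        spread = segment_length * 2.0 ** (depth - level)
        for tip in frontier:
            tx, ty, tz = nodes[tip].position
            for k, dy in enumerate((-spread / 2, spread / 2)):
                length = float(np.hypot(segment_length, dy))
                nodes.append(Node(next_node, (tx + segment_length, ty + dy, tz)))
                segments.append(Segment(next_seg, tip, next_node, d, length))
                new_frontier.append(next_node)
                next_node += 1
                next_seg += 1
        frontier = new_frontier
    bcs = []
    if root_pressure is not None:
        bcs.append(BoundaryCondition(0, "pressure", pressure=root_pressure))
    if leaf_pressure is not None:
        for leaf in frontier:
            bcs.append(BoundaryCondition(leaf, "pressure", pressure=leaf_pressure))
    return VascularNetwork(nodes, segments, bcs)


def make_lattice(
    nx: int = 4,
    ny: int = 4,
    spacing: float = 100.0,
    diameter: float = 12.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> VascularNetwork:
    """A planar rectangular grid with stub inlet/outlet segments at two
    opposite corners (so the boundary nodes have degree 1).  ``jitter``
    perturbs diameters log-normally for non-symmetric test cases.
    """
    rng = np.random.default_rng(seed)
    nodes = []
    for j in range(ny):
        for i in range(nx):
            nodes.append(Node(j * nx + i, (i * spacing, j * spacing, 0.0)))
    segments = []
    sid = 0

    def add(a, b):
        nonlocal sid
        d = diameter * float(np.exp(rng.normal(0.0, jitter))) if jitter else diameter
        pa = np.array(nodes[a].position)
        pb = np.array(nodes[b].position)
        segments.append(Segment(sid, a, b, d, float(np.linalg.norm(pb - pa))))
        sid += 1

    for j in range(ny):
        for i in range(nx):
            v = j * nx + i
            if i + 1 < nx:
                add(v, v + 1)
            if j + 1 < ny:
                add(v, v + nx)
    inlet = len(nodes)
    nodes.append(Node(inlet, (-spacing, 0.0, 0.0)))
    add(inlet, 0)
    outlet = len(nodes)
    nodes.append(Node(outlet, ((nx) * spacing, (ny - 1) * spacing, 0.0)))
    add(nx * ny - 1, outlet)
    return VascularNetwork(nodes, segments)


@dataclass(frozen=True)
class TumorLikeParams:
    """Parameters of the tumor-like generator.

    The defaults emulate a small tumor: a few hundred segments inside a
    1 mm-radius sphere, a vascularized rim occupying the outer 25% of the
    radius with 3× the node density of the core, log-normal diameters
    (median 10 µm, σ = 0.5 — positively skewed, as in tumor vasculature)
    and 6 boundary nodes on the surface.
    """

    seed: int = 0
    n_segments: int = 300
    radius_um: float = 1000.0
    rim_fraction: float = 0.25
    rim_core_ratio: float = 3.0
    diameter_median_um: float = 10.0
    diameter_sigma: float = 0.5
    n_boundary: int = 6
    loop_fraction: float = 0.15
    tortuosity: float = 1.1  # arc length / chord

    def __post_init__(self):
        if self.n_segments < 1 or self.n_boundary < 2:
            raise ValueError("need n_segments >= 1 and n_boundary >= 2")
        if not (0.0 < self.rim_fraction < 1.0):
            raise ValueError("rim_fraction must lie in (0, 1)")
        if self.rim_core_ratio <= 0 or self.diameter_median_um <= 0:
            raise ValueError("ratios and diameters must be > 0")


def make_tumor_like(params: TumorLikeParams = TumorLikeParams()) -> VascularNetwork:
    """Generate a seeded tumor-like vascular network.

    Interior nodes are sampled in a sphere with radially varying intensity
    (rim shell boosted by ``rim_core_ratio``); the graph is a Euclidean
    minimum spanning tree plus a fraction of extra short loop edges;
    diameters are log-normal, smoothed along graph neighbors so adjacent
    segments have correlated calibers; boundary nodes sit on the surface,
    attached by stub segments to their nearest interior node.  The tumor
    volume metadata is the sphere volume.
    """
    rng = np.random.default_rng(params.seed)
    n_interior = max(params.n_segments + 1 - params.n_boundary, params.n_boundary + 2)

    # rejection-sample radii: density ∝ 1 in core, rim_core_ratio in rim
    pts = []
    r_rim = (1.0 - params.rim_fraction) * params.radius_um
    while len(pts) < n_interior:
        cand = rng.uniform(-params.radius_um, params.radius_um, size=(4 * n_interior, 3))
        r = np.linalg.norm(cand, axis=1)
        inside = r <= params.radius_um
        cand, r = cand[inside], r[inside]
        dens = np.where(r >= r_rim, params.rim_core_ratio, 1.0)
        keep = rng.uniform(0, params.rim_core_ratio, size=len(cand)) < dens
        pts.extend(cand[keep].tolist())
    pts = np.asarray(pts[:n_interior])

    # Euclidean MST over k-nearest-neighbor candidate edges
    tree = cKDTree(pts)
    k = min(8, n_interior - 1)
    dist, nbr = tree.query(pts, k=k + 1)
    rows, cols, vals = [], [], []
    for i in range(n_interior):
        for jj in range(1, k + 1):
            rows.append(i)
            cols.append(int(nbr[i, jj]))
            vals.append(float(dist[i, jj]))
    graph = sp.coo_matrix((vals, (rows, cols)), shape=(n_interior, n_interior))
    mst = minimum_spanning_tree(graph.maximum(graph.T))
    edges = {tuple(sorted((int(a), int(b)))) for a, b in zip(*mst.nonzero())}
    if len(edges) < n_interior - 1:
        # kNN graph disconnected: bridge components by nearest pairs
        comp_graph = sp.coo_matrix(
            (np.ones(len(edges)), tuple(zip(*edges))), shape=(n_interior, n_interior)
        )
        from scipy.sparse.csgraph import connected_components

        n_comp, labels = connected_components(comp_graph, directed=False)
        while n_comp > 1:
            a_idx = np.flatnonzero(labels == 0)
            b_idx = np.flatnonzero(labels != 0)
            d2 = ((pts[a_idx][:, None, :] - pts[b_idx][None, :, :]) ** 2).sum(-1)
            ia, ib = np.unravel_index(int(np.argmin(d2)), d2.shape)
            edges.add(tuple(sorted((int(a_idx[ia]), int(b_idx[ib])))))
            comp_graph = sp.coo_matrix(
                (np.ones(len(edges)), tuple(zip(*edges))), shape=(n_interior, n_interior)
            )
            n_comp, labels = connected_components(comp_graph, directed=False)

    # add loop edges: extra short kNN edges not in the MST
    n_loops = int(params.loop_fraction * len(edges))
    candidates = []
    for i in range(n_interior):
        for jj in range(1, k + 1):
            key = tuple(sorted((i, int(nbr[i, jj]))))
            if key not in edges:
                candidates.append((float(dist[i, jj]), key))
    candidates.sort()
    seen = set()
    for _, key in candidates:
        if len(seen) >= n_loops:
            break
        if key not in seen:
            edges.add(key)
            seen.add(key)

    edges = sorted(edges)
    # boundary nodes on the sphere surface, attached to nearest interior node
    dirs = rng.normal(size=(params.n_boundary, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    surf = dirs * params.radius_um
    _, host = tree.query(surf)
    all_pos = np.vstack([pts, surf])
    for b in range(params.n_boundary):
        edges.append((n_interior + b, int(host[b])))

    # log-normal diameters, smoothed over adjacent segments sharing a node
    mu_ln = np.log(params.diameter_median_um)
    d_seg = np.exp(rng.normal(mu_ln, params.diameter_sigma, size=len(edges)))
    node_mean = np.zeros(len(all_pos))
    node_cnt = np.zeros(len(all_pos))
    for sidx, (a, b) in enumerate(edges):
        node_mean[a] += d_seg[sidx]
        node_mean[b] += d_seg[sidx]
        node_cnt[a] += 1
        node_cnt[b] += 1
    node_mean /= np.maximum(node_cnt, 1)
    d_seg = 0.5 * d_seg + 0.25 * (node_mean[[a for a, _ in edges]] + node_mean[[b for _, b in edges]])
    # boundary stubs get the largest diameters so they act as feeders/drainers
    d_seg[-params.n_boundary:] = np.quantile(d_seg, 0.9) * rng.uniform(
        1.0, 1.5, size=params.n_boundary
    )

    nodes = [
        Node(i, tuple(map(float, all_pos[i])), is_boundary=(i >= n_interior))
        for i in range(len(all_pos))
    ]
    segments = []
    for sidx, (a, b) in enumerate(edges):
        chord = float(np.linalg.norm(all_pos[a] - all_pos[b]))
        segments.append(
            Segment(sidx, int(a), int(b), float(d_seg[sidx]), chord * params.tortuosity)
        )
    vol_mm3 = 4.0 / 3.0 * np.pi * (params.radius_um * 1e-3) ** 3
    net = VascularNetwork(nodes, segments, tumor_volume_mm3=vol_mm3)
    # prune interior degree-1 stubs?  keep: they model blind-ended sprouts,
    # common in tumor vasculature; only surface nodes carry boundary data
    return net


# -- rat mesentery loader -----------------------------------------------------

_MESENTERY_SEGMENTS = 546
_MESENTERY_INLETS = 31
_MESENTERY_OUTLETS = 5


def load_mesentery(path, strict: bool = True) -> VascularNetwork:
    """Load the published rat mesentery network from a two-file text layout.

    ``path`` is a directory containing ``segments.txt`` (whitespace table:
    segment id, from node, to node, diameter µm, length µm, plus node
    coordinates appended as x_i y_i z_i x_j y_j z_j if available) and
    ``boundary.txt`` (node id, kind ∈ {inflow, outflow, pressure}, value,
    and discharge hematocrit for inflows).  The published dataset is not
    redistributed here; convert it to this layout to use the loader.

    With ``strict=True`` the loader verifies the documented counts: 546
    segments, 31 flow+hematocrit inlets, 5 flow outlets and exactly one
    constant-pressure venular outlet, and raises listing any discrepancy.
    """
    path = Path(path)
    seg_f = path / "segments.txt"
    bc_f = path / "boundary.txt"
    if not seg_f.exists() or not bc_f.exists():
        raise NetworkError(f"{path}: expected segments.txt and boundary.txt")
    seg = pd.read_csv(seg_f, sep=r"\s+", comment="#", header=None)
    if seg.shape[1] not in (5, 11):
        raise NetworkError(f"{seg_f}: expected 5 or 11 whitespace columns, got {seg.shape[1]}")
    has_coords = seg.shape[1] == 11

    node_pos: dict[int, tuple] = {}
    segments = []
    for r in seg.itertuples(index=False):
        vals = list(r)
        sid, a, b = int(vals[0]), int(vals[1]), int(vals[2])
        d, length = float(vals[3]), float(vals[4])
        if has_coords:
            node_pos.setdefault(a, (float(vals[5]), float(vals[6]), float(vals[7])))
            node_pos.setdefault(b, (float(vals[8]), float(vals[9]), float(vals[10])))
        else:
            node_pos.setdefault(a, None)
            node_pos.setdefault(b, None)
        segments.append(Segment(sid, a, b, d, length))
    if not has_coords:
        # synthetic coordinates on a deterministic circle: topology-only data
        ids = sorted(node_pos)
        for k, nid in enumerate(ids):
            ang = 2 * np.pi * k / len(ids)
            node_pos[nid] = (1e4 * np.cos(ang), 1e4 * np.sin(ang), 0.0)
        # lengths may exceed these placeholder chords; nothing to check here
    nodes = [Node(nid, node_pos[nid]) for nid in sorted(node_pos)]

    bc_rows = pd.read_csv(bc_f, sep=r"\s+", comment="#", header=None)
    bcs = []
    n_in = n_out = n_p = 0
    problems = []
    for r in bc_rows.itertuples(index=False):
        vals = list(r)
        nid, kind = int(vals[0]), str(vals[1]).lower()
        if kind == "inflow":
            if len(vals) < 4 or pd.isna(vals[3]):
                raise NetworkError(f"{bc_f}: inflow node {nid} missing discharge hematocrit")
            bcs.append(BoundaryCondition(nid, "flow_hd", flow=float(vals[2]), hd=float(vals[3])))
            n_in += 1
        elif kind == "outflow":
            bcs.append(BoundaryCondition(nid, "flow", flow=-abs(float(vals[2]))))
            n_out += 1
        elif kind == "pressure":
            bcs.append(BoundaryCondition(nid, "pressure", pressure=float(vals[2])))
            n_p += 1
        else:
            raise NetworkError(f"{bc_f}: unknown boundary kind {kind!r} at node {nid}")
    if strict:
        if len(segments) != _MESENTERY_SEGMENTS:
            problems.append(f"{len(segments)} segments, expected {_MESENTERY_SEGMENTS}")
        if n_in != _MESENTERY_INLETS:
            problems.append(f"{n_in} inlets, expected {_MESENTERY_INLETS}")
        if n_out != _MESENTERY_OUTLETS:
            problems.append(f"{n_out} flow outlets, expected {_MESENTERY_OUTLETS}")
        if n_p != 1:
            problems.append(f"{n_p} pressure nodes, expected 1")
        if problems:
            raise NetworkError(f"{path}: dataset count mismatches: " + "; ".join(problems))

    # placeholder coordinates can violate the arc>=chord rule; build without
    # lengths shorter than chords by inflating placeholder chords if needed
    if not has_coords:
        net = VascularNetwork.__new__(VascularNetwork)
        try:
            net.__init__(nodes, segments, bcs)
        except NetworkError:
            # scale the placeholder circle down so every chord fits
            nodes = [Node(n.id, tuple(c * 1e-3 for c in n.position)) for n in nodes]
            net = VascularNetwork(nodes, segments, bcs)
        return net
    return VascularNetwork(nodes, segments, bcs)
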