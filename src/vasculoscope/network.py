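"""Vascular network data model and structural validation.

A :class:`VascularNetwork` is a geometric graph: nodes carry 3D positions in
µm, segments carry a diameter and a (centerline arc) length in µm.  Segment
length may exceed the straight-line distance between its endpoints because
skeletonized vessels are curved.  Boundary nodes — network inlets/outlets —
are degree-1 nodes and may carry a boundary condition (a pressure, a flow,
or a flow plus discharge hematocrit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "Segment",
    "BoundaryCondition",
    "VascularNetwork",
    "NetworkDiagnostics",
    "NetworkError",
    "validate_network",
]

#: slack allowed when checking length >= chord, relative
_CHORD_RTOL = 1e-9


class NetworkError(ValueError):
    """Structural or schema violation in a vascular network."""


@dataclass(frozen=True)
class Node:
    """A branching or boundary point of the vascular graph."""

    id: int
    position: tuple[float, float, float]  # µm, world coordinates (x, y, z)
    is_boundary: bool = False


@dataclass(frozen=True)
class Segment:
    """A vessel segment between two nodes.

    ``length`` is the centerline arc length and must be at least the chord
    (Euclidean endpoint distance); ``diameter`` is the mean lumen diameter.
    Both in µm.
    """

    id: int
    node_i: int
    node_j: int
    diameter: float
    length: float


@dataclass(frozen=True)
class BoundaryCondition:
    """Boundary data at a degree-1 node.

    kind is one of ``pressure`` (mmHg), ``flow`` (µl/s, signed, inflow
    positive) or ``flow_hd`` (flow plus discharge hematocrit in [0, 1]).
    """

    node_id: int
    kind: str  # {"pressure", "flow", "flow_hd"}
    pressure: float | None = None  # mmHg
    flow: float | None = None  # µl/s, inflow positive
    hd: float | None = None  # discharge hematocrit fraction

    def __post_init__(self) -> None:
        if self.kind not in ("pressure", "flow", "flow_hd"):
            raise NetworkError(f"unknown boundary kind {self.kind!r} at node {self.node_id}")
        has_p = self.pressure is not None
        has_q = self.flow is not None
        if has_p == has_q:
            raise NetworkError(
                f"boundary node {self.node_id}: exactly one of pressure/flow required"
            )
        if self.kind == "pressure" and not has_p:
            raise NetworkError(f"boundary node {self.node_id}: kind=pressure needs a pressure")
        if self.kind in ("flow", "flow_hd") and not has_q:
            raise NetworkError(f"boundary node {self.node_id}: kind={self.kind} needs a flow")
        if self.kind == "flow_hd":
            if self.hd is None:
                raise NetworkError(f"boundary node {self.node_id}: kind=flow_hd needs hd")
            if not (0.0 <= self.hd <= 1.0):
                raise NetworkError(f"boundary node {self.node_id}: hd {self.hd} outside [0, 1]")


class VascularNetwork:
    """Validated vascular graph with array-backed storage.

    Parameters
    ----------
    nodes : sequence of Node
    segments : sequence of Segment
    boundary_conditions : sequence of BoundaryCondition, optional
    tumor_volume_mm3 : float, optional
        Tumor (tissue) volume the network perfuses, mm³.  Needed for volume
        density and for oxygen tissue mass.

    Notes
    -----
    Node ``is_boundary`` flags are recomputed from the topology: a boundary
    node is a degree-1 node.  Self-loops are rejected; parallel segments
    between the same node pair are allowed (they occur in real skeletons).
    """

    def __init__(
        self,
        nodes,
        segments,
        boundary_conditions=(),
        tumor_volume_mm3: float | None = None,
    ) -> None:
        nodes = list(nodes)
        segments = list(segments)
        node_ids = np.asarray([n.id for n in nodes], dtype=np.int64)
        if len(node_ids) == 0:
            raise NetworkError("network has no nodes")
        if len(np.unique(node_ids)) != len(node_ids):
            dup = node_ids[_duplicated(node_ids)]
            raise NetworkError(f"duplicate node ids: {sorted(set(dup.tolist()))}")
        positions = np.asarray([n.position for n in nodes], dtype=float)
        if positions.shape != (len(nodes), 3):
            raise NetworkError("node positions must be 3-vectors")
        if not np.all(np.isfinite(positions)):
            bad = node_ids[~np.isfinite(positions).all(axis=1)]
            raise NetworkError(f"non-finite positions at nodes {bad.tolist()}")

        self.node_ids = node_ids
        self.positions = positions
        self._index = {int(i): k for k, i in enumerate(node_ids)}

        seg_ids = np.asarray([s.id for s in segments], dtype=np.int64)
        if len(seg_ids) and len(np.unique(seg_ids)) != len(seg_ids):
            dup = seg_ids[_duplicated(seg_ids)]
            raise NetworkError(f"duplicate segment ids: {sorted(set(dup.tolist()))}")
        self.segment_ids = seg_ids
        self.seg_nodes = np.asarray(
            [(s.node_i, s.node_j) for s in segments], dtype=np.int64
        ).reshape(len(segments), 2)
        self.diameters = np.asarray([s.diameter for s in segments], dtype=float)
        self.lengths = np.asarray([s.length for s in segments], dtype=float)

        for s in segments:
            if s.node_i == s.node_j:
                raise NetworkError(f"segment {s.id}: self-loop at node {s.node_i}")
            for nid in (s.node_i, s.node_j):
                if nid not in self._index:
                    raise NetworkError(f"segment {s.id}: dangling node reference {nid}")
            if not s.diameter > 0:
                raise NetworkError(f"segment {s.id}: diameter {s.diameter} must be > 0")
            if not s.length > 0:
                raise NetworkError(f"segment {s.id}: length {s.length} must be > 0")
        if len(segments):
            chord = np.linalg.norm(
                self.positions[self.endpoint_indices[:, 0]]
                - self.positions[self.endpoint_indices[:, 1]],
                axis=1,
            )
            short = self.lengths < chord * (1.0 - _CHORD_RTOL)
            if np.any(short):
                bad = self.segment_ids[short]
                raise NetworkError(
                    f"segments {bad.tolist()}: arc length shorter than endpoint chord"
                )

        flagged = np.asarray([bool(n.is_boundary) for n in nodes])
        self._explicit_boundary = node_ids[flagged] if flagged.any() else None

        self.boundary_conditions: dict[int, BoundaryCondition] = {}
        for bc in boundary_conditions:
            if bc.node_id not in self._index:
                raise NetworkError(f"boundary condition references unknown node {bc.node_id}")
            if bc.node_id in self.boundary_conditions:
                raise NetworkError(f"duplicate boundary condition at node {bc.node_id}")
            self.boundary_conditions[int(bc.node_id)] = bc
        self.tumor_volume_mm3 = tumor_volume_mm3

    # -- topology ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)

    @property
    def endpoint_indices(self) -> np.ndarray:
        """(M, 2) array of node *indices* (not ids) per segment."""
        idx = getattr(self, "_endpoint_idx", None)
        if idx is None:
            idx = np.asarray(
                [[self._index[int(i)], self._index[int(j)]] for i, j in self.seg_nodes],
                dtype=np.int64,
            ).reshape(self.n_segments, 2)
            self._endpoint_idx = idx
        return idx

    def node_index(self, node_id: int) -> int:
        return self._index[int(node_id)]

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_segments:
            np.add.at(deg, self.endpoint_indices.ravel(), 1)
        return deg

    @property
    def boundary_node_ids(self) -> np.ndarray:
        """Ids of boundary (inlet/outlet) nodes.

        Explicit ``is_boundary`` flags take precedence when any node
        carries one; otherwise every degree-1 node counts as boundary.
        The distinction matters for networks with blind-ended sprouts:
        those are degree-1 but carry no boundary data and no flow.
        """
        if self._explicit_boundary is not None:
            return self._explicit_boundary
        return self.node_ids[self.degrees == 1]

    def chord_lengths(self) -> np.ndarray:
        p = self.positions
        e = self.endpoint_indices
        return np.linalg.norm(p[e[:, 0]] - p[e[:, 1]], axis=1)

    def to_nodes_segments(self) -> tuple[list[Node], list[Segment]]:
        boundary = set(int(b) for b in self.boundary_node_ids)
        nodes = [
            Node(int(i), tuple(map(float, p)), int(i) in boundary)
            for i, p in zip(self.node_ids, self.positions)
        ]
        segments = [
            Segment(int(s), int(a), int(b), float(d), float(length))
            for s, (a, b), d, length in zip(
                self.segment_ids, self.seg_nodes, self.diameters, self.lengths
            )
        ]
        return nodes, segments


def _duplicated(a: np.ndarray) -> np.ndarray:
    _, inv, counts = np.unique(a, return_inverse=True, return_counts=True)
    return counts[inv] > 1


@dataclass
class NetworkDiagnostics:
    """Structural report from :func:`validate_network` (never raises)."""

    n_nodes: int
    n_segments: int
    n_components: int
    n_boundary_nodes: int
    degree_histogram: dict[int, int]
    duplicate_segment_pairs: list[tuple[int, int]]
    zero_length_segments: list[int] = field(default_factory=list)
    zero_diameter_segments: list[int] = field(default_factory=list)
    isolated_nodes: list[int] = field(default_factory=list)
    boundary_nodes_not_degree1: list[int] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return (
            (self.n_components - 1)
            + len(self.duplicate_segment_pairs) * 0  # informational only
            + len(self.zero_length_segments)
            + len(self.zero_diameter_segments)
            + len(self.isolated_nodes)
            + len(self.boundary_nodes_not_degree1)
        )


def validate_network(net: VascularNetwork) -> NetworkDiagnostics:
    """Report structural diagnostics without mutating the network.

    Counts connected components and boundary (degree-1) nodes, builds the
    degree histogram and lists duplicate segment node-pairs, degenerate
    segments and isolated nodes.  Boundary-condition nodes that are not
    degree 1 are flagged.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    deg = net.degrees
    hist: dict[int, int] = {}
    for d in deg:
        hist[int(d)] = hist.get(int(d), 0) + 1

    if net.n_segments:
        e = net.endpoint_indices
        adj = sp.coo_matrix(
            (np.ones(net.n_segments), (e[:, 0], e[:, 1])),
            shape=(net.n_nodes, net.n_nodes),
        )
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = net.n_nodes

    pairs = {}
    dup_pairs = []
    for sid, (a, b) in zip(net.segment_ids, net.seg_nodes):
        key = (int(min(a, b)), int(max(a, b)))
        if key in pairs:
            dup_pairs.append(key)
        pairs[key] = int(sid)

    bad_bc = sorted(
        {
            int(nid)
            for nid in (*net.boundary_conditions, *net.boundary_node_ids)
            if deg[net.node_index(nid)] != 1
        }
    )

    return NetworkDiagnostics(
        n_nodes=net.n_nodes,
        n_segments=net.n_segments,
        n_components=int(n_comp),
        n_boundary_nodes=int(np.sum(deg == 1)),
        degree_histogram=hist,
        duplicate_segment_pairs=sorted(set(dup_pairs)),
        zero_length_segments=net.segment_ids[net.lengths <= 0].tolist(),
        zero_diameter_segments=net.segment_ids[net.diameters <= 0].tolist(),
        isolated_nodes=net.node_ids[deg == 0].tolist(),
        boundary_nodes_not_degree1=bad_bc,
    )
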