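"""Reading and writing vascular networks and per-segment attribute tables.

Formats
-------
csv
    A directory with three files:
    ``nodes.csv`` (id,x,y,z — µm), ``segments.csv``
    (id,node_i,node_j,diameter_um,length_um) and optional ``boundary.csv``
    (node_id,kind,pressure_mmHg,flow_ul_s,hd).
json
    One file holding the same records plus optional ``tumor_volume_mm3``.
amira_spatialgraph
    Amira/Avizo SpatialGraph ASCII (read only).  Segment length is the
    polyline arc length over ``EdgePointCoordinates``; diameter is twice the
    mean of the per-point ``thickness`` (radius) array.

Attribute export writes per-segment scalar tables as CSV or as VTK legacy
polydata (one polyline cell per segment, one CELL_DATA scalar array per
column) for 3D rendering.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    BoundaryCondition,
    NetworkError,
    Node,
    Segment,
    VascularNetwork,
)

__all__ = ["read_network", "write_network", "write_attributes", "read_amira_spatialgraph"]

log = logging.getLogger(__name__)

_BC_COLUMNS = ["node_id", "kind", "pressure_mmHg", "flow_ul_s", "hd"]


def read_network(path, format: str = "csv") -> VascularNetwork:
    """Read a vascular network.

    Parameters
    ----------
    path : str or Path
        Directory (csv) or file (json, amira_spatialgraph).
    format : {"csv", "json", "amira_spatialgraph"}
    """
    path = Path(path)
    if format == "csv":
        return _read_csv_dir(path)
    if format == "json":
        return _read_json(path)
    if format == "amira_spatialgraph":
        return read_amira_spatialgraph(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: VascularNetwork, path, format: str = "csv") -> None:
    """Write a network in the csv directory schema or as a single json file."""
    path = Path(path)
    nodes, segments = net.to_nodes_segments()
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        nd = pd.DataFrame(
            {
                "id": [n.id for n in nodes],
                "x": [n.position[0] for n in nodes],
                "y": [n.position[1] for n in nodes],
                "z": [n.position[2] for n in nodes],
                "is_boundary": [int(n.is_boundary) for n in nodes],
            }
        )
        nd.to_csv(path / "nodes.csv", index=False, float_format="%.10g")
        sd = pd.DataFrame(
            {
                "id": [s.id for s in segments],
                "node_i": [s.node_i for s in segments],
                "node_j": [s.node_j for s in segments],
                "diameter_um": [s.diameter for s in segments],
                "length_um": [s.length for s in segments],
            }
        )
        sd.to_csv(path / "segments.csv", index=False, float_format="%.10g")
        if net.boundary_conditions:
            bd = pd.DataFrame(
                [
                    {
                        "node_id": bc.node_id,
                        "kind": bc.kind,
                        "pressure_mmHg": bc.pressure,
                        "flow_ul_s": bc.flow,
                        "hd": bc.hd,
                    }
                    for bc in net.boundary_conditions.values()
                ],
                columns=_BC_COLUMNS,
            )
            bd.to_csv(path / "boundary.csv", index=False, float_format="%.10g")
        return
    if format == "json":
        doc = {
            "nodes": [
                {"id": n.id, "position": list(n.position), "is_boundary": n.is_boundary}
                for n in nodes
            ],
            "segments": [
                {
                    "id": s.id,
                    "node_i": s.node_i,
                    "node_j": s.node_j,
                    "diameter_um": s.diameter,
                    "length_um": s.length,
                }
                for s in segments
            ],
            "boundary_conditions": [
                {
                    "node_id": bc.node_id,
                    "kind": bc.kind,
                    "pressure_mmHg": bc.pressure,
                    "flow_ul_s": bc.flow,
                    "hd": bc.hd,
                }
                for bc in net.boundary_conditions.values()
            ],
        }
        if net.tumor_volume_mm3 is not None:
            doc["tumor_volume_mm3"] = net.tumor_volume_mm3
        path.write_text(json.dumps(doc, indent=1))
        return
    raise ValueError(f"unknown network format {format!r}")


def _read_csv_dir(path: Path) -> VascularNetwork:
    nodes_f = path / "nodes.csv"
    segs_f = path / "segments.csv"
    if not nodes_f.exists() or not segs_f.exists():
        raise NetworkError(f"{path}: expected nodes.csv and segments.csv")
    nd = pd.read_csv(nodes_f)
    sd = pd.read_csv(segs_f)
    for col in ("id", "x", "y", "z"):
        if col not in nd.columns:
            raise NetworkError(f"{nodes_f}: missing column {col!r}")
    for col in ("id", "node_i", "node_j", "diameter_um", "length_um"):
        if col not in sd.columns:
            raise NetworkError(f"{segs_f}: missing column {col!r}")
    has_flag = "is_boundary" in nd.columns
    nodes = [
        Node(
            int(r.id),
            (float(r.x), float(r.y), float(r.z)),
            bool(r.is_boundary) if has_flag else False,
        )
        for r in nd.itertuples()
    ]
    segments = [
        Segment(int(r.id), int(r.node_i), int(r.node_j), float(r.diameter_um), float(r.length_um))
        for r in sd.itertuples()
    ]
    bcs = []
    bc_f = path / "boundary.csv"
    if bc_f.exists():
        bd = pd.read_csv(bc_f)
        bcs = [_bc_from_row(r, bc_f) for r in bd.itertuples()]
    return VascularNetwork(nodes, segments, bcs)


def _bc_from_row(r, src) -> BoundaryCondition:
    def opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    try:
        return BoundaryCondition(
            node_id=int(r.node_id),
            kind=str(r.kind),
            pressure=opt(getattr(r, "pressure_mmHg", None)),
            flow=opt(getattr(r, "flow_ul_s", None)),
            hd=opt(getattr(r, "hd", None)),
        )
    except NetworkError as e:
        raise NetworkError(f"{src}: row {r.Index}: {e}") from e


def _read_json(path: Path) -> VascularNetwork:
    doc = json.loads(Path(path).read_text())
    try:
        nodes = [
            Node(
                int(n["id"]),
                tuple(float(c) for c in n["position"]),
                bool(n.get("is_boundary", False)),
            )
            for n in doc["nodes"]
        ]
        segments = [
            Segment(
                int(s["id"]),
                int(s["node_i"]),
                int(s["node_j"]),
                float(s["diameter_um"]),
                float(s["length_um"]),
            )
            for s in doc["segments"]
        ]
    except (KeyError, TypeError, ValueError) as e:
        raise NetworkError(f"{path}: malformed record: {e}") from e
    bcs = [
        BoundaryCondition(
            node_id=int(b["node_id"]),
            kind=str(b["kind"]),
            pressure=b.get("pressure_mmHg"),
            flow=b.get("flow_ul_s"),
            hd=b.get("hd"),
        )
        for b in doc.get("boundary_conditions", [])
    ]
    return VascularNetwork(nodes, segments, bcs, tumor_volume_mm3=doc.get("tumor_volume_mm3"))


# -- Amira SpatialGraph ASCII -------------------------------------------------

_SECTION_RE = re.compile(r"@(\d+)")


def read_amira_spatialgraph(path) -> VascularNetwork:
    """Read an Amira/Avizo HxSpatialGraph ASCII file.

    Parses ``VertexCoordinates``, ``EdgeConnectivity``, ``NumEdgePoints``,
    ``EdgePointCoordinates`` and per-point ``thickness`` (radius).  Each edge
    becomes one segment whose length is the polyline arc length and whose
    diameter is twice the mean thickness over its points.
    """
    text = Path(path).read_text()
    if "AmiraMesh" not in text.splitlines()[0]:
        raise NetworkError(f"{path}: not an AmiraMesh ASCII file")

    counts = {}
    for kind in ("VERTEX", "EDGE", "POINT"):
        m = re.search(rf"define\s+{kind}\s+(\d+)", text)
        if not m:
            raise NetworkError(f"{path}: missing 'define {kind}' declaration")
        counts[kind] = int(m.group(1))

    # map data-section markers to field names from the declaration block
    decl = {}
    for m in re.finditer(
        r"(VERTEX|EDGE|POINT)\s*\{\s*(?:float|int)\s*(?:\[\d+\])?\s*(\w+)\s*\}\s*@(\d+)", text
    ):
        decl[int(m.group(3))] = (m.group(1), m.group(2))

    # split trailing data blocks: "@k\n<numbers...>" until next "@"
    data: dict[int, np.ndarray] = {}
    for m in re.finditer(r"^@(\d+)\s*$", text, flags=re.MULTILINE):
        k = int(m.group(1))
        start = m.end()
        nxt = re.search(r"^@\d+\s*$", text[start:], flags=re.MULTILINE)
        block = text[start : start + nxt.start()] if nxt else text[start:]
        vals = np.array(block.split(), dtype=float) if block.strip() else np.empty(0)
        data[k] = vals

    def field(name: str) -> np.ndarray:
        for k, (_, fname) in decl.items():
            if fname.lower() == name.lower():
                if k not in data:
                    raise NetworkError(f"{path}: data section @{k} ({name}) missing")
                return data[k]
        raise NetworkError(f"{path}: field {name!r} not declared")

    verts = field("VertexCoordinates").reshape(counts["VERTEX"], 3)
    conn = field("EdgeConnectivity").astype(np.int64).reshape(counts["EDGE"], 2)
    npts = field("NumEdgePoints").astype(np.int64).reshape(counts["EDGE"])
    pts = field("EdgePointCoordinates").reshape(counts["POINT"], 3)
    thick = field("thickness").reshape(counts["POINT"])

    nodes = [Node(i, tuple(map(float, verts[i]))) for i in range(counts["VERTEX"])]
    segments = []
    off = 0
    for e in range(counts["EDGE"]):
        k = int(npts[e])
        poly = pts[off : off + k]
        radii = thick[off : off + k]
        off += k
        arc = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
        segments.append(
            Segment(
                id=e,
                node_i=int(conn[e, 0]),
                node_j=int(conn[e, 1]),
                diameter=2.0 * float(np.mean(radii)),
                length=arc,
            )
        )
    return VascularNetwork(nodes, segments)


# -- attribute export ---------------------------------------------------------


def write_attributes(net: VascularNetwork, table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a per-segment scalar table, keyed by segment id.

    CSV: one row per segment.  ``vtk_polyline``: legacy VTK ASCII polydata
    with one line cell per segment and one CELL_DATA scalar array per
    column, for rendering networks color-coded by simulated quantities.
    NaN values are written verbatim (with a logged warning).
    """
    path = Path(path)
    table = table.copy()
    if "segment_id" in table.columns:
        table = table.set_index("segment_id")
    missing = [int(s) for s in net.segment_ids if int(s) not in set(table.index)]
    if missing:
        raise NetworkError(f"attribute table missing segment ids {missing}")
    table = table.loc[[int(s) for s in net.segment_ids]]
    if table.isna().any().any():
        log.warning("attribute table contains NaN values; written verbatim")

    if format == "csv":
        out = table.reset_index().rename(columns={"index": "segment_id"})
        if "segment_id" not in out.columns:
            out.insert(0, "segment_id", [int(s) for s in net.segment_ids])
        out.to_csv(path, index=False, float_format="%.10g")
        return
    if format == "vtk_polyline":
        _write_vtk_polyline(net, table, path)
        return
    raise ValueError(f"unknown attribute format {format!r}")


def _write_vtk_polyline(net: VascularNetwork, table: pd.DataFrame, path: Path) -> None:
    e = net.endpoint_indices
    lines = [
        "# vtk DataFile Version 3.0",
        "vascular network attributes",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {net.n_nodes} float",
    ]
    for p in net.positions:
        lines.append(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
    lines.append(f"LINES {net.n_segments} {3 * net.n_segments}")
    for a, b in e:
        lines.append(f"2 {a} {b}")
    lines.append(f"CELL_DATA {net.n_segments}")
    for col in table.columns:
        lines.append(f"SCALARS {col} float 1")
        lines.append("LOOKUP_TABLE default")
        for v in table[col].to_numpy():
            lines.append(f"{float(v):.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
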