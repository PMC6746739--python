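"""Standard-format I/O: TIFF stacks, GraphML/CSV vessel graphs, VTK PolyData.

Vessel graphs round-trip through a pair of CSV tables (nodes.csv,
segments.csv) or GraphML; networks are additionally exported as legacy
ASCII VTK PolyData (one polyline per vessel, per-vessel scalars as cell
data) for 3D viewers such as ParaView.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .core import BinaryMask, BlockMap, Node, Segment, VesselGraph, VoxelVolume

SEGMENT_COLUMNS = [
    "id",
    "node_a",
    "node_b",
    "length_um",
    "volume_um3",
    "diameter_um",
    "generation_in",
    "generation_out",
    "class",
]


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def read_tiff(path, voxel_size: float) -> VoxelVolume:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    return VoxelVolume(data, voxel_size, bit_depth=data.dtype.itemsize * 8)


def write_tiff(path, volume) -> None:
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(str(path), np.ascontiguousarray(data))


def write_mask_tiff(path, mask: BinaryMask) -> None:
    tifffile.imwrite(str(path), mask.data.astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# vessel graphs
# ---------------------------------------------------------------------------

def graph_to_dataframes(graph: VesselGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        {
            "id": [n.id for n in graph.nodes.values()],
            "x_um": [n.position[0] for n in graph.nodes.values()],
            "y_um": [n.position[1] for n in graph.nodes.values()],
            "z_um": [n.position[2] for n in graph.nodes.values()],
            "kind": [n.kind for n in graph.nodes.values()],
            "is_inlet": [n.id == graph.inlet_node for n in graph.nodes.values()],
            "is_outlet": [n.id == graph.outlet_node for n in graph.nodes.values()],
        }
    )
    segs = pd.DataFrame(
        {
            "id": [s.id for s in graph.segments.values()],
            "node_a": [s.node_a for s in graph.segments.values()],
            "node_b": [s.node_b for s in graph.segments.values()],
            "length_um": [s.length_um for s in graph.segments.values()],
            "volume_um3": [s.volume_um3 for s in graph.segments.values()],
            "diameter_um": [s.diameter_um for s in graph.segments.values()],
            "generation_in": [s.generation_from_inlet for s in graph.segments.values()],
            "generation_out": [
                s.generation_from_outlet for s in graph.segments.values()
            ],
            "class": [s.vessel_class for s in graph.segments.values()],
        }
    )
    return nodes, segs[SEGMENT_COLUMNS]


def write_graph_csv(graph: VesselGraph, out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes, segs = graph_to_dataframes(graph)
    npath = out_dir / "nodes.csv"
    spath = out_dir / "segments.csv"
    nodes.to_csv(npath, index=False, float_format="%.6f")
    segs.to_csv(spath, index=False, float_format="%.6f")
    return npath, spath


def read_graph_csv(nodes_path, segments_path) -> VesselGraph:
    nodes = pd.read_csv(nodes_path)
    segs = pd.read_csv(segments_path)
    graph = VesselGraph()
    for row in nodes.itertuples():
        graph.add_node(
            Node(int(row.id), np.array([row.x_um, row.y_um, row.z_um]), row.kind)
        )
        if bool(row.is_inlet):
            graph.inlet_node = int(row.id)
        if bool(row.is_outlet):
            graph.outlet_node = int(row.id)
    for row in segs.itertuples():
        gi = None if pd.isna(row.generation_in) else int(row.generation_in)
        go = None if pd.isna(row.generation_out) else int(row.generation_out)
        graph.add_segment(
            Segment(
                int(row.id),
                int(row.node_a),
                int(row.node_b),
                float(row.length_um),
                float(row.diameter_um),
                float(row.volume_um3),
                points=np.vstack(
                    [
                        graph.nodes[int(row.node_a)].position,
                        graph.nodes[int(row.node_b)].position,
                    ]
                ),
                generation_from_inlet=gi,
                generation_from_outlet=go,
                vessel_class=row[-1],  # 'class' is renamed by itertuples
            )
        )
    return graph


def write_graphml(graph: VesselGraph, path) -> None:
    g = nx.MultiGraph()
    g.graph["inlet_node"] = -1 if graph.inlet_node is None else graph.inlet_node
    g.graph["outlet_node"] = -1 if graph.outlet_node is None else graph.outlet_node
    for n in graph.nodes.values():
        g.add_node(
            n.id,
            x_um=float(n.position[0]),
            y_um=float(n.position[1]),
            z_um=float(n.position[2]),
            kind=n.kind,
        )
    for s in graph.segments.values():
        g.add_edge(
            s.node_a,
            s.node_b,
            key=s.id,
            length_um=float(s.length_um),
            volume_um3=float(s.volume_um3),
            diameter_um=float(s.diameter_um),
            vessel_class=s.vessel_class,
        )
    nx.write_graphml(g, str(path))


def read_graphml(path) -> VesselGraph:
    g = nx.read_graphml(str(path), force_multigraph=True)
    graph = VesselGraph()
    for nid, attrs in g.nodes(data=True):
        graph.add_node(
            Node(
                int(nid),
                np.array([attrs["x_um"], attrs["y_um"], attrs["z_um"]]),
                attrs["kind"],
            )
        )
    for a, b, key, attrs in g.edges(keys=True, data=True):
        graph.add_segment(
            Segment(
                int(key),
                int(a),
                int(b),
                float(attrs["length_um"]),
                float(attrs["diameter_um"]),
                float(attrs["volume_um3"]),
                points=np.vstack(
                    [graph.nodes[int(a)].position, graph.nodes[int(b)].position]
                ),
                vessel_class=attrs.get("vessel_class", "unclassified"),
            )
        )
    inlet = int(g.graph.get("inlet_node", -1))
    outlet = int(g.graph.get("outlet_node", -1))
    graph.inlet_node = None if inlet < 0 else inlet
    graph.outlet_node = None if outlet < 0 else outlet
    return graph


# ---------------------------------------------------------------------------
# VTK PolyData (legacy ASCII), one polyline per vessel
# ---------------------------------------------------------------------------

def write_vtk_polydata(
    graph: VesselGraph,
    path,
    cell_scalars: Optional[dict[str, dict[int, float]]] = None,
) -> None:
    """Legacy ASCII VTK PolyData export for 3D viewers.

    ``cell_scalars`` maps field name → {segment id → value} (e.g. pressure,
    velocity); diameters are always written.
    """
    points: list[np.ndarray] = []
    lines: list[list[int]] = []
    seg_order = list(graph.segments.values())
    for seg in seg_order:
        pts = seg.points
        if pts is None:
            pts = np.vstack(
                [graph.nodes[seg.node_a].position, graph.nodes[seg.node_b].position]
            )
        start = len(points)
        points.extend(pts)
        lines.append(list(range(start, start + len(pts))))

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvessel network\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        fh.write(f"CELL_DATA {len(lines)}\n")
        fields = {"diameter_um": {s.id: s.diameter_um for s in seg_order}}
        if cell_scalars:
            fields.update(cell_scalars)
        for name, values in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for seg in seg_order:
                fh.write(f"{values.get(seg.id, float('nan')):.6g}\n")


# ---------------------------------------------------------------------------
# block maps and sidecars
# ---------------------------------------------------------------------------

def write_blockmap(bm: BlockMap, out_base) -> tuple[Path, Path]:
    """Write a block map as TIFF (grid) and long-format CSV."""
    out_base = Path(out_base)
    tpath = out_base.with_suffix(".tiff")
    cpath = out_base.with_suffix(".csv")
    tifffile.imwrite(
        str(tpath),
        np.nan_to_num(bm.values).astype(np.float32),
        photometric="minisblack",
    )
    idx = np.argwhere(np.isfinite(bm.values))
    df = pd.DataFrame(
        {
            "bi": idx[:, 0],
            "bj": idx[:, 1],
            "bk": idx[:, 2],
            f"{bm.quantity}_{bm.units.replace('/', '_per_')}": bm.values[
                idx[:, 0], idx[:, 1], idx[:, 2]
            ],
        }
    )
    df.to_csv(cpath, index=False, float_format="%.6g")
    return tpath, cpath


def write_json_sidecar(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in obj.__dict__.items() if not k.startswith("_")}
    raise TypeError(f"not JSON serializable: {type(obj)}")
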