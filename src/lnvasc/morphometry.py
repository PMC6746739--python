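"""Network morphometry, vessel classification and blockwise maps.

Vessel classes follow the generation/diameter rule used for whole lymph-node
networks: vessels up to ten generations of branching from the main arteriole
(resp. venule) that are more than 10 µm in diameter are arteries (resp.
veins); everything else is a capillary.  Generations count the minimum number
of branch points traversed from the inlet (resp. outlet) end node, evaluated
by 0–1 breadth-first search so the rule is well defined on loopy networks.
"""
from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import BinaryMask, BlockMap, VesselGraph, block_grid_shape
from .hemodynamics import HemodynamicSolution
from .starling import TransmuralFlowField
from .units import UM2_PER_MM2, UM3_PER_MM3, UM_PER_CM


@dataclass
class MorphometrySummary:
    """Whole-network statistics in the units conventional for organ atlases."""

    n_vessels: int
    n_branch_points: int
    mean_diameter_um: float
    mean_length_um: float
    network_length_cm: float
    network_volume_mm3: float
    network_surface_area_mm2: float          # Σ πdL (per-vessel lateral area)
    isosurface_area_mm2: Optional[float]     # blockwise marching-cubes total
    surface_area_density_um2_per_um3: float
    volume_fraction_pct: float
    vessel_density_per_mm3: float
    feeding_arteriole_diameter_um: float
    main_vein_diameter_um: float
    ln_volume_mm3: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_network(
    graph: VesselGraph,
    ln_volume_mm3: float,
    isosurface_area_mm2: Optional[float] = None,
) -> MorphometrySummary:
    """Table-style network statistics against a reference organ volume.

    Surface area is reported two ways on purpose: the per-vessel Σ πdL used
    by the exchange model, and (when available) the blockwise isosurface
    total, which includes the voxel-scale corrugation of the wall.  Density
    and fraction denominators use ``ln_volume_mm3``.
    """
    if not graph.segments:
        raise ValueError("empty graph")
    net_vol_mm3 = graph.total_volume_um3() / UM3_PER_MM3
    if ln_volume_mm3 <= net_vol_mm3:
        raise ValueError(
            f"reference volume {ln_volume_mm3} mm³ must exceed the network "
            f"volume {net_vol_mm3:.4g} mm³"
        )
    lengths = np.array([s.length_um for s in graph.segments.values()])
    diams = np.array([s.diameter_um for s in graph.segments.values()])
    sa_um2 = graph.total_lateral_surface_um2()
    n_branch = sum(1 for n in graph.nodes.values() if n.kind == "branch")

    def _boundary_diameter(node_id: Optional[int]) -> float:
        if node_id is None:
            return float("nan")
        incident = graph.incident_segments(node_id)
        return max(s.diameter_um for s in incident) if incident else float("nan")

    return MorphometrySummary(
        n_vessels=len(graph.segments),
        n_branch_points=n_branch,
        mean_diameter_um=float(diams.mean()),
        mean_length_um=float(lengths.mean()),
        network_length_cm=float(lengths.sum() / UM_PER_CM),
        network_volume_mm3=net_vol_mm3,
        network_surface_area_mm2=sa_um2 / UM2_PER_MM2,
        isosurface_area_mm2=isosurface_area_mm2,
        surface_area_density_um2_per_um3=sa_um2 / (ln_volume_mm3 * UM3_PER_MM3),
        volume_fraction_pct=100.0 * net_vol_mm3 / ln_volume_mm3,
        vessel_density_per_mm3=len(graph.segments) / ln_volume_mm3,
        feeding_arteriole_diameter_um=_boundary_diameter(graph.inlet_node),
        main_vein_diameter_um=_boundary_diameter(graph.outlet_node),
        ln_volume_mm3=ln_volume_mm3,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _generations_from(graph: VesselGraph, root_node: int) -> dict[int, int]:
    """Minimum branch-point count from ``root_node`` to every segment (0–1 BFS)."""
    adjacency: dict[int, list[int]] = {}
    for sid, seg in graph.segments.items():
        adjacency.setdefault(seg.node_a, []).append(sid)
        adjacency.setdefault(seg.node_b, []).append(sid)
    is_branch = {nid: (n.kind == "branch") for nid, n in graph.nodes.items()}

    gen: dict[int, int] = {}
    dq: deque = deque()
    for sid in adjacency.get(root_node, []):
        gen[sid] = 0
        dq.append(sid)
    while dq:
        sid = dq.popleft()
        seg = graph.segments[sid]
        for node in (seg.node_a, seg.node_b):
            step = 1 if is_branch[node] else 0
            for tid in adjacency[node]:
                if tid == sid:
                    continue
                cand = gen[sid] + step
                if tid not in gen or cand < gen[tid]:
                    gen[tid] = cand
                    if step == 0:
                        dq.appendleft(tid)
                    else:
                        dq.append(tid)
    return gen


def classify_vessels(
    graph: VesselGraph,
    max_generation: int = 10,
    min_trunk_diameter_um: float = 10.0,
) -> VesselGraph:
    """Assign artery/vein/capillary classes in place (and return the graph).

    artery iff generation_from_inlet ≤ 10 and d > 10 µm; vein symmetrically
    from the outlet; a vessel satisfying both goes to the side with the
    smaller generation count (artery on an exact tie).  Everything else —
    including large-diameter vessels deeper than ten generations — is a
    capillary.  Vessels unreachable from inlet or outlet are left
    ``unclassified`` and reported with a warning.
    """
    if graph.inlet_node is None or graph.outlet_node is None:
        raise ValueError("graph must have designated inlet and outlet")
    gen_in = _generations_from(graph, graph.inlet_node)
    gen_out = _generations_from(graph, graph.outlet_node)
    unreachable = []
    for sid, seg in graph.segments.items():
        gi = gen_in.get(sid)
        go = gen_out.get(sid)
        seg.generation_from_inlet = gi
        seg.generation_from_outlet = go
        if gi is None or go is None:
            seg.vessel_class = "unclassified"
            unreachable.append(sid)
            continue
        is_artery = gi <= max_generation and seg.diameter_um > min_trunk_diameter_um
        is_vein = go <= max_generation and seg.diameter_um > min_trunk_diameter_um
        if is_artery and is_vein:
            seg.vessel_class = "artery" if gi <= go else "vein"
        elif is_artery:
            seg.vessel_class = "artery"
        elif is_vein:
            seg.vessel_class = "vein"
        else:
            seg.vessel_class = "capillary"
    if unreachable:
        warnings.warn(
            f"{len(unreachable)} segment(s) unreachable from inlet/outlet "
            "were left unclassified"
        )
    return graph


def aggregate_by_class(
    graph: VesselGraph, flow_field: Optional[TransmuralFlowField] = None
) -> dict[str, dict[str, float]]:
    """Percent contribution of each class to volume, wall area and flux.

    Returns ``{'volume_pct': {...}, 'surface_area_pct': {...},
    'transmural_flow_pct': {...}}``; each row sums to 100.  Unclassified
    vessels trigger a warning and are reported in their own column.
    """
    classes = sorted({s.vessel_class for s in graph.segments.values()})
    if "unclassified" in classes:
        warnings.warn("unclassified segments present; reported separately")
    vol = {c: 0.0 for c in classes}
    sa = {c: 0.0 for c in classes}
    for seg in graph.segments.values():
        vol[seg.vessel_class] += seg.volume_um3
        sa[seg.vessel_class] += seg.lateral_surface_um2

    def _pct(d: dict[str, float]) -> dict[str, float]:
        tot = sum(d.values())
        if tot == 0:
            return {c: 0.0 for c in d}
        return {c: 100.0 * v / tot for c, v in d.items()}

    out = {"volume_pct": _pct(vol), "surface_area_pct": _pct(sa)}
    if flow_field is not None:
        flux = {c: 0.0 for c in classes}
        for sid, j in flow_field.segment_flux.items():
            flux[graph.segments[sid].vessel_class] += j
        out["transmural_flow_pct"] = _pct(flux)
    return out


# ---------------------------------------------------------------------------
# blockwise maps
# ---------------------------------------------------------------------------

def apportion_polyline(
    points: np.ndarray, block_size_um: float, nblocks: tuple[int, int, int]
) -> dict[tuple[int, int, int], float]:
    """Exact length of a polyline inside each cubic block.

    Every straight piece is split analytically at the grid planes, so the
    per-block lengths sum to the polyline length to machine precision.
    """
    out: dict[tuple[int, int, int], float] = {}
    pts = np.asarray(points, float)
    for a in range(len(pts) - 1):
        p, q = pts[a], pts[a + 1]
        seg_len = float(np.linalg.norm(q - p))
        if seg_len == 0:
            continue
        ts = {0.0, 1.0}
        for axis in range(3):
            lo = min(p[axis], q[axis])
            hi = max(p[axis], q[axis])
            k0 = int(np.floor(lo / block_size_um)) + 1
            k1 = int(np.floor(hi / block_size_um))
            for k in range(k0, k1 + 1):
                plane = k * block_size_um
                if q[axis] != p[axis]:
                    t = (plane - p[axis]) / (q[axis] - p[axis])
                    if 0.0 < t < 1.0:
                        ts.add(float(t))
        ts = sorted(ts)
        for t0, t1 in zip(ts[:-1], ts[1:]):
            mid = p + 0.5 * (t0 + t1) * (q - p)
            block = tuple(
                int(np.clip(np.floor(mid[axis] / block_size_um), 0, nblocks[axis] - 1))
                for axis in range(3)
            )
            out[block] = out.get(block, 0.0) + seg_len * (t1 - t0)
    return out


def block_pressure_and_flow_maps(
    graph: VesselGraph,
    solution: HemodynamicSolution,
    flow_field: Optional[TransmuralFlowField],
    block_size_voxels: int,
    voxel_size_um: float,
    volume_shape: tuple[int, int, int],
) -> dict[str, BlockMap]:
    """Blockwise surface area, wall-area-weighted pressure and transmural flow.

    Per-vessel quantities are apportioned to blocks by centerline length
    inside each block, so block totals conserve the network totals exactly.
    """
    nblocks = block_grid_shape(volume_shape, block_size_voxels)
    bs_um = block_size_voxels * voxel_size_um
    sa = np.zeros(nblocks)
    sap = np.zeros(nblocks)  # Σ S·P for the weighted mean
    jmap = np.zeros(nblocks)
    for sid, seg in graph.segments.items():
        pts = seg.points
        if pts is None:
            pts = np.vstack(
                [graph.nodes[seg.node_a].position, graph.nodes[seg.node_b].position]
            )
        parts = apportion_polyline(pts, bs_um, nblocks)
        total_len = sum(parts.values())
        if total_len == 0:
            continue
        p_b = solution.segment_mean_pressure.get(sid, np.nan)
        for block, ln in parts.items():
            frac = ln / total_len
            s_here = np.pi * seg.diameter_um * ln
            sa[block] += s_here
            sap[block] += s_here * p_b
            if flow_field is not None:
                jmap[block] += flow_field.segment_flux[sid] * frac
    with np.errstate(invalid="ignore"):
        pmap = np.where(sa > 0, sap / np.where(sa > 0, sa, 1.0), np.nan)
    maps = {
        "surface_area": BlockMap(block_size_voxels, sa, "surface_area", "um2", voxel_size_um),
        "pressure": BlockMap(block_size_voxels, pmap, "pressure", "mmHg", voxel_size_um),
    }
    if flow_field is not None:
        maps["transmural_flow"] = BlockMap(
            block_size_voxels, jmap, "transmural_flow", "nL/min", voxel_size_um
        )
    return maps


def estimate_ln_volume(mask: BinaryMask) -> float:
    """Reference organ volume (mm³) as the convex hull of the foreground.

    The hull of the vascular foreground is a practical proxy for the organ
    envelope when no separate tissue segmentation exists; a user-supplied
    override is accepted everywhere a reference volume is consumed.
    Degenerate inputs (fewer than 4 non-coplanar points) report 0 with a
    warning instead of crashing.
    """
    coords = np.argwhere(mask.data)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    # hull only needs candidate extreme points: use the foreground surface
    from scipy import ndimage

    surface = mask.data & ~ndimage.binary_erosion(mask.data)
    pts = np.argwhere(surface).astype(float) * mask.voxel_size
    if pts.shape[0] < 4:
        warnings.warn("degenerate mask: fewer than 4 hull points, volume 0")
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (coplanar/collinear) mask: hull volume 0")
        return 0.0
    return float(hull.volume / UM3_PER_MM3)
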