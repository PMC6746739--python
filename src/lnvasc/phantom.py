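"""Synthetic vascular phantoms with known ground truth.

A phantom is a branching arterial tree joined to a venous tree through
capillary bridges, with diameters following Murray's law
(d_parent^k = Σ d_child^k), rasterized to a voxel volume as capsules
(cylinders with hemispherical caps).  Both the ground-truth graph and the
voxel volume are returned, so every image-processing and modelling stage
downstream can be validated against known geometry.

The generator aims for structural plausibility of a small-organ
microvascular bed — diameter range of a few to tens of µm, loopy
arterio-venous connectivity, sub-micron voxels — not for hemodynamic
realism of any particular organ.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import Node, Segment, VesselGraph, VoxelVolume


@dataclass
class PhantomSpec:
    """Parameters of a synthetic arterio-venous phantom.

    Diameters and lengths in µm.  ``branching_depth`` counts segment
    generations (depth 1 = a single unbranched root segment).  The Murray
    exponent k sets the child diameters at symmetric bifurcations:
    d_child = d_parent · 2^(−1/k).
    """

    root_artery_diameter: float = 30.0
    root_vein_diameter: float = 40.0
    branching_depth: int = 3
    murray_exponent: float = 3.0
    capillary_diameter_range: tuple[float, float] = (6.0, 10.0)
    capillary_connection_density: float = 1.0
    domain_size: tuple[float, float, float] = (500.0, 400.0, 400.0)
    voxel_size: float = 0.81
    noise_sd: float = 0.0
    random_seed: int = 0
    # geometry knobs (not part of the imaging model); the length/diameter
    # ratio is kept small so the two trees stay in their own halves of the
    # domain and the capillaries bridge the middle
    length_diameter_ratio: float = 2.5
    branch_angle_deg: float = 45.0
    jitter: float = 0.12  # relative angular jitter at bifurcations
    foreground_intensity: float = 200.0
    background_intensity: float = 20.0

    def __post_init__(self) -> None:
        if self.root_artery_diameter <= 0 or self.root_vein_diameter <= 0:
            raise ValueError("root diameters must be positive")
        if self.branching_depth < 1:
            raise ValueError("branching_depth must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.murray_exponent <= 0:
            raise ValueError("murray_exponent must be positive")
        lo, hi = self.capillary_diameter_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid capillary_diameter_range")

    def terminal_diameter(self, root_diameter: float) -> float:
        return root_diameter * 2.0 ** (-(self.branching_depth - 1) / self.murray_exponent)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector perpendicular to ``direction``, azimuth drawn from rng."""
    d = _unit(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, ref))
    w = np.cross(d, u)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * u + np.sin(phi) * w


def generate_vascular_tree(
    spec: PhantomSpec,
    side: str,
    root_position: Optional[np.ndarray] = None,
    root_direction: Optional[np.ndarray] = None,
) -> VesselGraph:
    """Build a rooted symmetric bifurcating tree on one side of the circulation.

    The root node is the inlet (``side='artery'``) or outlet (``side='vein'``).
    Terminal diameters below 2·voxel_size are rejected: such vessels could not
    be resolved by the imaging model.
    """
    if side not in ("artery", "vein"):
        raise ValueError("side must be 'artery' or 'vein'")
    root_d = spec.root_artery_diameter if side == "artery" else spec.root_vein_diameter
    term_d = spec.terminal_diameter(root_d)
    if term_d < 2.0 * spec.voxel_size:
        raise ValueError(
            f"branching_depth={spec.branching_depth} gives terminal diameter "
            f"{term_d:.2f} µm < 2 voxels ({2 * spec.voxel_size:.2f} µm); "
            "reduce depth, enlarge the root, or shrink the voxel"
        )
    domain = np.asarray(spec.domain_size, dtype=float)
    if root_position is None:
        frac = 0.08 if side == "artery" else 0.92
        root_position = domain * np.array([frac, 0.5, 0.5])
    if root_direction is None:
        root_direction = np.array([1.0, 0.0, 0.0]) if side == "artery" else np.array([-1.0, 0.0, 0.0])
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.random_seed, 0 if side == "artery" else 1])
    )

    graph = VesselGraph()
    root = graph.add_node(Node(0, np.asarray(root_position, float), "end"))
    if side == "artery":
        graph.inlet_node = root.id
    else:
        graph.outlet_node = root.id

    angle = np.deg2rad(spec.branch_angle_deg)

    def grow(parent_node: Node, direction: np.ndarray, diameter: float, depth: int) -> None:
        length = spec.length_diameter_ratio * diameter
        tip_pos = parent_node.position + _unit(direction) * length
        is_terminal = depth == spec.branching_depth
        tip = graph.add_node(
            Node(graph.new_node_id(), tip_pos, "end" if is_terminal else "branch")
        )
        graph.add_segment(
            Segment(
                graph.new_segment_id(),
                parent_node.id,
                tip.id,
                length_um=float(length),
                diameter_um=float(diameter),
                volume_um3=float(np.pi * diameter**2 * length / 4.0),
                points=np.vstack([parent_node.position, tip_pos]),
            )
        )
        if is_terminal:
            return
        child_d = diameter * 2.0 ** (-1.0 / spec.murray_exponent)
        perp = _perpendicular(direction, rng)
        for sign in (+1.0, -1.0):
            a = angle * (1.0 + spec.jitter * rng.uniform(-1.0, 1.0))
            child_dir = _unit(np.cos(a) * _unit(direction) + sign * np.sin(a) * perp)
            grow(tip, child_dir, child_d, depth + 1)

    grow(root, np.asarray(root_direction, float), root_d, 1)
    graph.validate()
    return graph


def _terminal_tips(graph: VesselGraph) -> list[int]:
    root = graph.inlet_node if graph.inlet_node is not None else graph.outlet_node
    return [n for n in graph.end_nodes() if n != root]


def connect_arteriovenous(
    arterial: VesselGraph, venous: VesselGraph, spec: PhantomSpec
) -> VesselGraph:
    """Merge the two trees with capillary bridges between their terminals.

    Each arterial terminal is paired with the nearest still-unused venous
    terminal (greedy, seed-jittered order); densities above 1 add extra
    random pairs, producing loops as in real capillary beds.  The merged
    graph has exactly one inlet and one outlet and is connected between them.
    """
    if arterial.inlet_node is None:
        raise ValueError("arterial tree has no inlet")
    if venous.outlet_node is None:
        raise ValueError("venous tree has no outlet")
    a_tips = _terminal_tips(arterial)
    v_tips = _terminal_tips(venous)
    n_pairs = min(len(a_tips), len(v_tips))
    n_conn = int(round(spec.capillary_connection_density * n_pairs))
    if n_conn < 1:
        raise ValueError(
            "capillary_connection_density too low: zero arterio-venous "
            "connections leave no flow path"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.random_seed, 2]))

    merged = VesselGraph()
    node_map: dict[tuple[str, int], int] = {}
    for tag, src in (("a", arterial), ("v", venous)):
        for node in src.nodes.values():
            nid = merged.add_node(
                Node(merged.new_node_id(), node.position.copy(), node.kind)
            ).id
            node_map[(tag, node.id)] = nid
        for seg in src.segments.values():
            merged.add_segment(
                Segment(
                    merged.new_segment_id(),
                    node_map[(tag, seg.node_a)],
                    node_map[(tag, seg.node_b)],
                    seg.length_um,
                    seg.diameter_um,
                    seg.volume_um3,
                    points=None if seg.points is None else seg.points.copy(),
                )
            )
    merged.inlet_node = node_map[("a", arterial.inlet_node)]
    merged.outlet_node = node_map[("v", venous.outlet_node)]

    # greedy nearest matching without replacement, order jittered by seed
    order = list(range(len(a_tips)))
    rng.shuffle(order)
    available = set(range(len(v_tips)))
    pairs: list[tuple[int, int]] = []
    for i in order[:n_pairs]:
        pa = arterial.nodes[a_tips[i]].position
        j = min(
            available,
            key=lambda j: float(np.linalg.norm(pa - venous.nodes[v_tips[j]].position)),
        )
        available.discard(j)
        pairs.append((a_tips[i], v_tips[j]))
    for _ in range(n_conn - len(pairs)):
        i = int(rng.integers(len(a_tips)))
        j = int(rng.integers(len(v_tips)))
        pairs.append((a_tips[i], v_tips[j]))

    for a_id, v_id in pairs:
        na = merged.nodes[node_map[("a", a_id)]]
        nv = merged.nodes[node_map[("v", v_id)]]
        length = float(np.linalg.norm(na.position - nv.position))
        if length <= 0:
            raise ValueError("coincident arterial and venous terminals")
        d = float(rng.uniform(*spec.capillary_diameter_range))
        merged.add_segment(
            Segment(
                merged.new_segment_id(),
                na.id,
                nv.id,
                length,
                d,
                float(np.pi * d**2 * length / 4.0),
                points=np.vstack([na.position, nv.position]),
                vessel_class="unclassified",
            )
        )

    # junction tips that gained capillaries are pass-through, not ends
    for node in merged.nodes.values():
        deg = merged.node_degree(node.id)
        if node.id in (merged.inlet_node, merged.outlet_node):
            node.kind = "end"
        elif deg == 1:
            node.kind = "end"
        elif deg == 2:
            node.kind = "through"
        else:
            node.kind = "branch"

    if not merged.is_connected_inlet_outlet():
        raise ValueError("merged phantom is not connected from inlet to outlet")
    merged.validate()
    return merged


def generate_phantom(spec: PhantomSpec) -> VesselGraph:
    """Convenience: arterial tree + venous tree + capillary bridges."""
    arterial = generate_vascular_tree(spec, "artery")
    venous = generate_vascular_tree(spec, "vein")
    return connect_arteriovenous(arterial, venous, spec)


def _rasterize_capsule(
    fg: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float, voxel: float,
    flat_caps: bool = False,
) -> None:
    """Mark voxels whose center lies within ``radius`` of the segment p0–p1."""
    shape = np.asarray(fg.shape)
    lo = np.floor((np.minimum(p0, p1) - radius) / voxel - 1).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + radius) / voxel + 1).astype(int)
    lo = np.clip(lo, 0, shape - 1)
    hi = np.clip(hi, 0, shape - 1)
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
    )
    centers = np.stack([ii, jj, kk], axis=-1) * voxel
    axis = p1 - p0
    L2 = float(axis @ axis)
    rel = centers - p0
    t = (rel @ axis) / L2
    tc = np.clip(t, 0.0, 1.0)
    closest = p0 + tc[..., None] * axis
    dist2 = np.sum((centers - closest) ** 2, axis=-1)
    inside = dist2 <= radius**2
    if flat_caps:
        inside &= (t >= 0.0) & (t <= 1.0)
    fg[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside


def rasterize_graph(
    graph: VesselGraph, spec: PhantomSpec, flat_caps: bool = False
) -> VoxelVolume:
    """Draw every segment as a capsule of its diameter into a grayscale volume.

    A voxel is foreground iff its center lies inside some capsule
    (voxel-center inclusion).  Gaussian noise of ``spec.noise_sd`` is added
    afterwards; with noise_sd = 0 exactly two intensities are present.
    Segments thinner than one voxel cannot be represented: they are skipped
    with a warning and listed in ``volume.meta['dropped_segments']``.
    """
    voxel = spec.voxel_size
    shape = tuple(int(round(s / voxel)) for s in spec.domain_size)
    margin = voxel
    domain = np.asarray(spec.domain_size, float)
    for seg in graph.segments.values():
        pts = seg.points
        if pts is None:
            raise ValueError(f"segment {seg.id} has no centerline points")
        r = seg.diameter_um / 2.0
        if np.any(pts - r < margin - 1e-9) or np.any(pts + r > domain - margin + 1e-9):
            raise ValueError(
                f"segment {seg.id} does not fit inside the domain with a "
                "1-voxel margin"
            )

    fg = np.zeros(shape, dtype=bool)
    dropped: list[int] = []
    for seg in graph.segments.values():
        if seg.diameter_um < voxel:
            dropped.append(seg.id)
            continue
        pts = seg.points
        for a in range(len(pts) - 1):
            _rasterize_capsule(
                fg, pts[a], pts[a + 1], seg.diameter_um / 2.0, voxel, flat_caps
            )
    if dropped:
        warnings.warn(
            f"{len(dropped)} segment(s) thinner than one voxel were not rasterized"
        )

    data = np.where(fg, spec.foreground_intensity, spec.background_intensity).astype(
        np.float64
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.random_seed, 3]))
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    vol = VoxelVolume(data=data, voxel_size=voxel)
    vol.meta["dropped_segments"] = dropped
    vol.meta["spec"] = replace(spec)
    return vol
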