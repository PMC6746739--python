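import numpy as np
import pytest

import lnvasc as lv
from lnvasc.core import Node, Segment, VesselGraph


def make_cylinder_graph(p0, p1, diameter):
    """Single-segment graph between two points (µm)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    g = VesselGraph()
    g.add_node(Node(0, p0, "end"))
    g.add_node(Node(1, p1, "end"))
    length = float(np.linalg.norm(p1 - p0))
    g.add_segment(
        Segment(
            0, 0, 1, length, diameter,
            np.pi * diameter**2 * length / 4.0,
            points=np.vstack([p0, p1]),
        )
    )
    g.inlet_node, g.outlet_node = 0, 1
    return g


@pytest.fixture
def cylinder_graph():
    return make_cylinder_graph([20.0, 30.0, 30.0], [180.0, 30.0, 30.0], 10.0)


@pytest.fixture
def small_phantom_spec():
    """Depth-2 arterio-venous phantom that rasterizes cleanly at 2 µm voxels."""
    return lv.PhantomSpec(
        branching_depth=2,
        root_artery_diameter=24.0,
        root_vein_diameter=30.0,
        capillary_diameter_range=(10.0, 12.0),
        domain_size=(360.0, 240.0, 240.0),
        voxel_size=2.0,
        random_seed=0,
    )


@pytest.fixture
def small_phantom(small_phantom_spec):
    return lv.generate_phantom(small_phantom_spec)


def make_line_graph(n_segments, diameter=10.0, length=100.0):
    """Chain of n segments from inlet to outlet."""
    g = VesselGraph()
    for i in range(n_segments + 1):
        kind = "end" if i in (0, n_segments) else "branch"
        g.add_node(Node(i, [i * length, 0.0, 0.0], kind))
    for i in range(n_segments):
        g.add_segment(
            Segment(
                i, i, i + 1, length, diameter,
                np.pi * diameter**2 * length / 4.0,
                points=np.array([[i * length, 0.0, 0.0], [(i + 1) * length, 0.0, 0.0]]),
            )
        )
    g.inlet_node, g.outlet_node = 0, n_segments
    return g
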