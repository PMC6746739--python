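"""Viscosity law, Poiseuille resistance, and the circuit solver."""
import math

import numpy as np
import pytest

import lnvasc as lv
from lnvasc.core import Node, Segment, VesselGraph
from lnvasc.hemodynamics import (
    HemoParams,
    apparent_viscosity,
    inflow_for_wall_shear_stress,
    relative_apparent_viscosity,
    segment_resistance,
    segment_velocity,
    solve_network_flow,
    wall_shear_stress,
)

from conftest import make_line_graph


def oracle_mu_rel(d, h):
    """Independent term-by-term transcription of the in-vivo viscosity law."""
    mu45 = 6.0 * math.exp(-0.085 * d) + 3.2 - 2.44 * math.exp(-0.06 * d**0.645)
    f = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + math.exp(-0.075 * d)) * (-1.0 + f) + f
    geom = (d / (d - 1.1)) ** 2
    return (1.0 + (mu45 - 1.0) * ((1 - h) ** c - 1) / ((1 - 0.45) ** c - 1) * geom) * geom


class TestViscosity:
    @pytest.mark.parametrize("h", [0.1, 0.45, 0.6])
    def test_matches_independent_transcription(self, h):
        for d in np.linspace(3.0, 100.0, 195):
            assert relative_apparent_viscosity(d, h) == pytest.approx(
                oracle_mu_rel(float(d), h), rel=1e-12
            )

    def test_large_diameter_asymptote(self):
        assert relative_apparent_viscosity(1e4, 0.45) == pytest.approx(3.2, rel=2e-3)

    def test_plasma_limit_hematocrit_zero(self):
        assert relative_apparent_viscosity(1e4, 0.0) == pytest.approx(1.0, rel=2e-3)

    def test_clamp_warns_then_rejects(self):
        with pytest.warns(UserWarning, match="clamp"):
            v = apparent_viscosity(2.0, min_diameter_clamp=3.0)
        assert np.isfinite(v) and v > 0
        with pytest.raises(ValueError):
            relative_apparent_viscosity(1.0)


class TestResistance:
    def test_closed_form_value(self):
        # d = 10 µm, L = 100 µm, µ = 1 mPa·s → 128·µ·L/(π d⁴) in SI
        r_si = 128 * 1e-3 * 100e-6 / (math.pi * (10e-6) ** 4)
        expected = r_si * (1e-9 / 60) / 133.322
        assert segment_resistance(10.0, 100.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_fourth_power_diameter_scaling(self):
        assert segment_resistance(20.0, 100.0, 1.0) == pytest.approx(
            segment_resistance(10.0, 100.0, 1.0) / 16.0, rel=1e-12
        )

    def test_series_additivity(self):
        g = make_line_graph(2, diameter=10.0, length=100.0)
        params = HemoParams(inflow=0.01, outlet_pressure=10.0, viscosity_model="newtonian")
        sol = solve_network_flow(g, params)
        r = segment_resistance(10.0, 100.0, params.newtonian_viscosity)
        assert sol.total_pressure_drop == pytest.approx(2 * r * 0.01, rel=1e-12)


class TestPointwiseFormulas:
    def test_velocity_closed_form_and_scaling(self):
        q, d = 0.22, 48.1
        v_si = (q * 1e-9 / 60) / (math.pi * (d * 1e-6) ** 2 / 4)
        assert segment_velocity(q, d) == pytest.approx(v_si * 1e3, rel=1e-12)
        assert segment_velocity(q, d / 2) == pytest.approx(4 * segment_velocity(q, d))
        assert segment_velocity(0.0, 10.0) == 0.0

    def test_wss_scaling_and_round_trip(self):
        assert wall_shear_stress(0.1, 5.0, 2.0) == pytest.approx(
            8 * wall_shear_stress(0.1, 10.0, 2.0), rel=1e-12
        )
        tau = wall_shear_stress(0.22, 48.1, 3.0)
        assert inflow_for_wall_shear_stress(48.1, 3.0, tau) == pytest.approx(0.22, rel=1e-12)


def _random_sp_tree(rng, depth):
    """Random tree whose terminals all drain into a single outlet node.

    Returns (graph, resistances-by-segment) for series-parallel reduction.
    """
    g = VesselGraph()
    inlet = g.add_node(Node(0, [0.0, 0.0, 0.0], "end")).id
    outlet_id = 10_000
    g.add_node(Node(outlet_id, [1e4, 0.0, 0.0], "end"))
    g.inlet_node, g.outlet_node = inlet, outlet_id

    def build(parent, d):
        if d == depth:
            children = [outlet_id]
        else:
            children = []
            for _ in range(int(rng.integers(1, 4))):
                nid = g.add_node(
                    Node(g.new_node_id() if g.new_node_id() != outlet_id else outlet_id + 1,
                         rng.uniform(0, 1000, 3), "branch")
                ).id
                children.append(nid)
        for c in children:
            g.add_segment(
                Segment(
                    g.new_segment_id(), parent, c,
                    float(rng.uniform(20, 200)), float(rng.uniform(5, 40)),
                    1.0 + float(rng.uniform(0, 1)),
                )
            )
            if c != outlet_id:
                build(c, d + 1)

    build(inlet, 1)
    return g


def _reduce_series_parallel(g, params):
    """Hand reduction: equivalent resistance inlet→outlet for trees whose
    terminals all meet at the outlet; returns predicted inlet pressure."""
    mus = {
        sid: (params.newtonian_viscosity if params.viscosity_model == "newtonian"
              else apparent_viscosity(s.diameter_um, params.hematocrit,
                                      params.plasma_viscosity))
        for sid, s in g.segments.items()
    }
    res = {
        sid: segment_resistance(s.diameter_um, s.length_um, mus[sid])
        for sid, s in g.segments.items()
    }
    children = {}
    for sid, s in g.segments.items():
        children.setdefault(s.node_a, []).append((sid, s.node_b))

    def equiv(node):
        if node == g.outlet_node:
            return 0.0
        inv = 0.0
        for sid, child in children[node]:
            inv += 1.0 / (res[sid] + equiv(child))
        return 1.0 / inv

    return params.outlet_pressure + params.inflow * equiv(g.inlet_node)


class TestSolver:
    def test_single_tube_exact(self, cylinder_graph):
        params = HemoParams(inflow=0.05, outlet_pressure=10.0, viscosity_model="newtonian")
        sol = solve_network_flow(cylinder_graph, params)
        r = segment_resistance(10.0, 160.0, params.newtonian_viscosity)
        assert sol.inlet_pressure == pytest.approx(10.0 + r * 0.05, rel=1e-12)
        assert sol.segment_flows[0] == pytest.approx(0.05, rel=1e-12)

    def test_parallel_tubes_split_inversely_to_resistance(self):
        g = VesselGraph()
        g.add_node(Node(0, [0, 0, 0], "end"))
        g.add_node(Node(1, [100, 0, 0], "end"))
        common = dict(points=None)
        g.add_segment(Segment(0, 0, 1, 100.0, 10.0, 1.0, **common))
        g.add_segment(Segment(1, 0, 1, 200.0, 10.0, 1.0, **common))  # 2R
        g.inlet_node, g.outlet_node = 0, 1
        sol = solve_network_flow(g, HemoParams(inflow=0.3, viscosity_model="newtonian"))
        assert sol.segment_flows[0] == pytest.approx(0.2, rel=1e-12)
        assert sol.segment_flows[1] == pytest.approx(0.1, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_series_parallel_reduction(self, seed):
        rng = np.random.default_rng(seed)
        g = _random_sp_tree(rng, depth=int(rng.integers(2, 5)))
        params = HemoParams(inflow=0.22, outlet_pressure=10.0)
        sol = solve_network_flow(g, params)
        assert sol.inlet_pressure == pytest.approx(
            _reduce_series_parallel(g, params), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_on_random_phantoms(self, seed):
        spec = lv.PhantomSpec(voxel_size=2.0, random_seed=seed,
                              branching_depth=int(2 + seed % 3),
                              capillary_connection_density=1.0 + 0.5 * (seed % 2))
        g = lv.generate_phantom(spec)
        params = HemoParams()
        sol = solve_network_flow(g, params)
        imbalance = {nid: 0.0 for nid in g.nodes}
        for sid, s in g.segments.items():
            q = sol.segment_flows[sid]
            imbalance[s.node_a] -= q
            imbalance[s.node_b] += q
        for nid, net in imbalance.items():
            if nid == g.inlet_node:
                assert net == pytest.approx(-params.inflow, abs=1e-9 * params.inflow)
            elif nid == g.outlet_node:
                assert net == pytest.approx(params.inflow, abs=1e-9 * params.inflow)
            else:
                assert abs(net) <= 1e-9 * params.inflow

    def test_pressures_monotone_on_tree_paths(self):
        rng = np.random.default_rng(5)
        g = _random_sp_tree(rng, depth=3)
        sol = solve_network_flow(g, HemoParams())
        lo, hi = sol.params.outlet_pressure, sol.inlet_pressure
        for p in sol.node_pressures.values():
            assert lo - 1e-9 <= p <= hi + 1e-9

    def test_disconnected_outlet_raises(self, cylinder_graph):
        g = cylinder_graph
        g.add_node(Node(5, [0, 100.0, 0], "end"))
        g.add_node(Node(6, [0, 200.0, 0], "end"))
        g.add_segment(Segment(9, 5, 6, 100.0, 10.0, 1.0))
        g.outlet_node = 6
        with pytest.raises(ValueError, match="disconnected"):
            solve_network_flow(g, HemoParams())
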