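"""Poiseuille network hemodynamics with diameter-dependent blood viscosity.

The network is treated as an electrical circuit: each vessel is a resistor
R = 128 µ_app L / (π d⁴) under laminar fully-developed flow, with the
apparent viscosity µ_app(d, H_D) from the empirical in-vivo
Fåhræus–Lindqvist law (Pries-type formulation).  Boundary conditions follow
the whole-organ convention: a fixed inflow through the feeding arteriole,
a fixed pressure at the main draining vein, and zero flow through every
other end point (vessels truncated at the imaging boundary).

Unit system: µm, mmHg, µL/min, mPa·s (see :mod:`lnvasc.units`); velocities
in mm/s, wall shear stress in dyn/cm².
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import VesselGraph
from .units import (
    DYN_PER_CM2_PER_PA,
    M3_PER_S_PER_UL_PER_MIN,
    M_PER_UM,
    PA_PER_MMHG,
    PA_S_PER_MPA_S,
)


@dataclass
class HemoParams:
    """Boundary conditions and blood rheology.

    inflow: blood flow through the feeding arteriole, µL/min.
    outlet_pressure: pressure at the main draining vein, mmHg.
    hematocrit: discharge hematocrit H_D entering the viscosity law.
    plasma_viscosity: mPa·s.
    min_diameter_clamp: diameters below this (µm) are clamped inside the
        viscosity law, which is singular at d = 1.1 µm.
    viscosity_model: 'pries' (diameter-dependent) or 'newtonian'
        (constant ``newtonian_viscosity``).
    """

    inflow: float = 0.22
    outlet_pressure: float = 10.0
    hematocrit: float = 0.45
    plasma_viscosity: float = 1.2
    min_diameter_clamp: float = 3.0
    viscosity_model: str = "pries"
    newtonian_viscosity: float = 3.0

    def __post_init__(self) -> None:
        if self.inflow <= 0:
            raise ValueError("inflow must be positive")
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.plasma_viscosity <= 0:
            raise ValueError("plasma_viscosity must be positive")
        if self.min_diameter_clamp <= 1.1:
            raise ValueError("min_diameter_clamp must exceed 1.1 µm")
        if self.viscosity_model not in ("pries", "newtonian"):
            raise ValueError("viscosity_model must be 'pries' or 'newtonian'")


@dataclass
class HemodynamicSolution:
    node_pressures: dict[int, float]          # mmHg
    segment_flows: dict[int, float]           # µL/min, node_a→node_b positive
    segment_mean_pressure: dict[int, float]   # mmHg
    segment_velocity: dict[int, float]        # mm/s
    segment_wss: dict[int, float]             # dyn/cm²
    inlet_pressure: float                     # mmHg
    total_pressure_drop: float                # mmHg
    params: HemoParams = field(default_factory=HemoParams)


def relative_apparent_viscosity(d_um, hematocrit: float = 0.45):
    """Relative apparent blood viscosity µ_rel(d, H_D) (in-vivo law).

    µ45(d) = 6·e^(−0.085 d) + 3.2 − 2.44·e^(−0.06·d^0.645)
    C(d)   = (0.8 + e^(−0.075 d))·(−1 + 1/(1 + 10⁻¹¹ d¹²)) + 1/(1 + 10⁻¹¹ d¹²)
    µ_rel  = [1 + (µ45 − 1)·((1 − H_D)^C − 1)/((1 − 0.45)^C − 1)·(d/(d−1.1))²]
             · (d/(d−1.1))²

    with d in µm.  The (d/(d−1.1))² factors account for the endothelial
    surface layer and make the law singular at d = 1.1 µm.
    """
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 1.1):
        raise ValueError("viscosity law is singular at d <= 1.1 µm")
    mu45 = 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    f = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + f) + f
    geom = (d / (d - 1.1)) ** 2
    h_term = ((1.0 - hematocrit) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)
    mu_rel = (1.0 + (mu45 - 1.0) * h_term * geom) * geom
    return mu_rel if mu_rel.shape else float(mu_rel)


def apparent_viscosity(
    d_um,
    hematocrit: float = 0.45,
    plasma_viscosity: float = 1.2,
    min_diameter_clamp: float = 3.0,
) -> float | np.ndarray:
    """Apparent viscosity in mPa·s; diameters below the clamp are clamped."""
    d = np.asarray(d_um, dtype=float)
    if np.any(d < min_diameter_clamp):
        warnings.warn(
            "diameters below the viscosity clamp "
            f"({min_diameter_clamp} µm) were clamped"
        )
        d = np.maximum(d, min_diameter_clamp)
    if np.any(d <= 1.1):
        raise ValueError("diameter <= 1.1 µm even after clamping")
    out = relative_apparent_viscosity(d, hematocrit) * plasma_viscosity
    return out if np.ndim(out) else float(out)


def segment_resistance(d_um: float, length_um: float, mu_mpas: float) -> float:
    """Poiseuille resistance R = 128 µ L / (π d⁴) in mmHg/(µL/min)."""
    if d_um <= 0 or length_um <= 0 or mu_mpas <= 0:
        raise ValueError("diameter, length and viscosity must be positive")
    r_si = (
        128.0
        * (mu_mpas * PA_S_PER_MPA_S)
        * (length_um * M_PER_UM)
        / (np.pi * (d_um * M_PER_UM) ** 4)
    )  # Pa·s/m³
    return float(r_si * M3_PER_S_PER_UL_PER_MIN / PA_PER_MMHG)


def segment_velocity(q_ul_min: float, d_um: float) -> float:
    """Mean cross-sectional velocity v = 4Q/(πd²) in mm/s (sign of Q kept)."""
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    q_si = q_ul_min * M3_PER_S_PER_UL_PER_MIN
    area = np.pi * (d_um * M_PER_UM) ** 2 / 4.0
    return float(q_si / area * 1e3)  # m/s → mm/s


def wall_shear_stress(q_ul_min: float, d_um: float, mu_mpas: float) -> float:
    """Poiseuille wall shear stress τ = 32 µ Q / (π d³) in dyn/cm²."""
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    q_si = q_ul_min * M3_PER_S_PER_UL_PER_MIN
    tau_pa = 32.0 * (mu_mpas * PA_S_PER_MPA_S) * q_si / (np.pi * (d_um * M_PER_UM) ** 3)
    return float(tau_pa * DYN_PER_CM2_PER_PA)


def inflow_for_wall_shear_stress(
    d_um: float, mu_mpas: float, tau_dyn_cm2: float = 10.0
) -> float:
    """Inflow Q = τ π d³ / (32 µ) (µL/min) giving the target feeding-artery WSS.

    Whole-organ inflow boundary conditions are conventionally chosen so the
    feeding arteriole carries a physiological wall shear stress (~10 dyn/cm²);
    this inverts the Poiseuille WSS formula for that convention.
    """
    if d_um <= 0 or mu_mpas <= 0:
        raise ValueError("diameter and viscosity must be positive")
    tau_pa = tau_dyn_cm2 / DYN_PER_CM2_PER_PA
    q_si = tau_pa * np.pi * (d_um * M_PER_UM) ** 3 / (32.0 * mu_mpas * PA_S_PER_MPA_S)
    return float(q_si / M3_PER_S_PER_UL_PER_MIN)


def _segment_viscosities(graph: VesselGraph, params: HemoParams) -> dict[int, float]:
    if params.viscosity_model == "newtonian":
        return {sid: params.newtonian_viscosity for sid in graph.segments}
    diam = np.array([s.diameter_um for s in graph.segments.values()])
    mus = apparent_viscosity(
        diam, params.hematocrit, params.plasma_viscosity, params.min_diameter_clamp
    )
    return dict(zip(graph.segments.keys(), np.atleast_1d(mus)))


def solve_network_flow(graph: VesselGraph, params: HemoParams) -> HemodynamicSolution:
    """Nodal-analysis solve of the vessel circuit.

    Unknowns are node pressures.  Mass conservation holds at every interior
    node; the inlet carries the fixed inflow, the outlet holds the fixed
    pressure, and truncated end points carry no source term (natural
    zero-flow).  Loops (capillary anastomoses) are handled by the sparse
    linear solve; nothing assumes a tree.
    """
    if graph.inlet_node is None or graph.outlet_node is None:
        raise ValueError("graph must have designated inlet and outlet nodes")
    g = graph.to_networkx()
    if not nx.has_path(g, graph.inlet_node, graph.outlet_node):
        comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise ValueError(
            f"inlet and outlet are disconnected (component sizes {comps})"
        )
    # nodes unreachable from the outlet have no pressure reference; solve only
    # the component containing inlet+outlet and report others as unsolved
    comp = nx.node_connected_component(g, graph.outlet_node)
    node_ids = sorted(comp)
    idx = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    mus = _segment_viscosities(graph, params)
    conduct: dict[int, float] = {}
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    for sid, seg in graph.segments.items():
        if seg.node_a not in idx or seg.node_b not in idx:
            continue
        r = segment_resistance(seg.diameter_um, seg.length_um, mus[sid])
        gcond = 1.0 / r
        conduct[sid] = gcond
        ia, ib = idx[seg.node_a], idx[seg.node_b]
        rows += [ia, ia, ib, ib]
        cols += [ia, ib, ib, ia]
        vals += [gcond, -gcond, gcond, -gcond]
    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    b[idx[graph.inlet_node]] = params.inflow
    iout = idx[graph.outlet_node]
    a.rows[iout] = [iout]
    a.data[iout] = [1.0]
    b[iout] = params.outlet_pressure
    pressures = spla.spsolve(a.tocsr(), b)

    # residual check on the conservation equations
    resid = a.tocsr() @ pressures - b
    resid[iout] = 0.0
    if np.max(np.abs(resid)) > 1e-8 * params.inflow:
        raise RuntimeError("linear solve residual exceeds tolerance")

    node_pressures = {nid: float(pressures[idx[nid]]) for nid in node_ids}
    flows, mean_p, vel, wss = {}, {}, {}, {}
    for sid, seg in graph.segments.items():
        if sid not in conduct:
            continue
        pa = node_pressures[seg.node_a]
        pb = node_pressures[seg.node_b]
        q = (pa - pb) * conduct[sid]
        flows[sid] = q
        mean_p[sid] = 0.5 * (pa + pb)
        vel[sid] = segment_velocity(q, seg.diameter_um)
        wss[sid] = wall_shear_stress(q, seg.diameter_um, mus[sid])

    inlet_p = node_pressures[graph.inlet_node]
    return HemodynamicSolution(
        node_pressures=node_pressures,
        segment_flows=flows,
        segment_mean_pressure=mean_p,
        segment_velocity=vel,
        segment_wss=wss,
        inlet_pressure=inlet_p,
        total_pressure_drop=inlet_p - params.outlet_pressure,
        params=params,
    )
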