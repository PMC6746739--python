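"""Published reference measurements of murine popliteal lymph-node vasculature.

Morphometric parameters of four whole-node blood-vessel networks measured
from corrosion casts by synchrotron µCT (0.81 µm voxels), bundled here so
cross-node summaries and worked hemodynamic examples can be computed without
the multi-gigabyte image stacks.  A "vessel" is the centerline segment
between two branching or end points.
"""
from __future__ import annotations

import pandas as pd

REFERENCE_NETWORKS = pd.DataFrame(
    {
        "network": ["LN1", "LN2", "LN3", "LN4"],
        "n_vessels": [10765, 6480, 2447, 3931],
        "n_branch_points": [6546, 3451, 1202, 3692],
        "mean_diameter_um": [8.98, 9.31, 10.27, 10.35],
        "mean_length_um": [40.4, 36.7, 66.0, 76.2],
        "network_length_cm": [43.5, 23.8, 16.2, 30.0],
        "network_volume_mm3": [0.060, 0.042, 0.073, 0.051],
        "network_surface_area_mm2": [14.9, 9.5, 11.3, 17.9],
        "surface_area_density_um2_per_um3": [0.0156, 0.00937, 0.0115, 0.0112],
        "volume_fraction_pct": [10.1, 4.2, 7.1, 3.2],
        "vessel_density_per_mm3": [11272, 6420, 2499, 2462],
        "feeding_arteriole_diameter_um": [48.1, 28.4, 26.6, 34.7],
        "main_vein_diameter_um": [63.4, 56.4, 58.2, 82.0],
    }
).set_index("network")

# Whole-network hemodynamic boundary conditions and results reported for LN1.
REFERENCE_INFLOW_UL_MIN = 0.22
REFERENCE_OUTLET_PRESSURE_MMHG = 10.0
REFERENCE_WSS_DYN_CM2 = 10.0
REFERENCE_PRESSURE_DROP_MMHG = 19.5

# Reported whole-node transmural-flow totals: P_lymph (mmHg) → ΣJ (nL/min).
REFERENCE_TRANSMURAL_TOTALS_NL_MIN = {4.0: 0.0, 20.0: 10.0, 30.0: 15.0}

# Reported class contributions for LN1 (percent of total; flux at P_lymph = 20 mmHg).
REFERENCE_CLASS_FRACTIONS = pd.DataFrame(
    {
        "artery": [13.9, 10.0, 3.0],
        "vein": [25.9, 13.8, 16.7],
        "capillary": [60.2, 76.2, 80.3],
    },
    index=["volume_pct", "surface_area_pct", "transmural_flow_pct"],
)
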