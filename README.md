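# lnvasc

Quantification of whole-organ blood-vessel networks from 3D image stacks,
with network hemodynamics and transmural blood–lymph fluid exchange.

`lnvasc` is aimed at the workflow used to characterise the vasculature of
small organs — prototypically a murine lymph node imaged by synchrotron µCT
of a corrosion cast at sub-micron voxels. It takes a grayscale or binary
stack (or a pre-extracted vessel graph) and produces:

1. **Vessel morphometry** — 8-bit conversion, 3×3×3 median filtering,
   artefact masking, Otsu segmentation, homotopic 3D thinning, and a vessel
   graph in which a *vessel* is the centerline segment between two branching
   or end points, with per-vessel pathlength *L*, lumen volume *V* (voxel
   count × voxel volume), volume-equivalent diameter *d* = 2√((V/L)/π) and
   wall area *S* = π d L, plus blockwise marching-cubes surface-area maps.
2. **Network hemodynamics** — an electrical-circuit (nodal-analysis) solve
   of Poiseuille flow, R = 128 µL/(π d⁴), using the empirical diameter- and
   hematocrit-dependent apparent blood viscosity µ(d, H_D)
   (Fåhræus–Lindqvist effect, in-vivo formulation), with a fixed inflow at
   the feeding arteriole, fixed pressure at the main draining vein, and zero
   flow at truncated endpoints. Outputs per-node pressures and per-vessel
   flows, velocities v = 4Q/(πd²) and wall shear stress τ = 32µQ/(πd³).
3. **Vessel classification** — artery/vein if within ten branching
   generations of the feeding arteriole/draining vein *and* more than 10 µm
   in diameter; capillary otherwise. Generations are counted by 0–1 BFS so
   the rule is well defined on loopy networks.
4. **Starling exchange** — per-vessel transmural flux
   J = Lp·S·[(P_lymph − P_b) − σ(π_lymph − π_blood)], lymph-pressure sweeps,
   the closed-form zero-crossing pressure, calibration of (Lp, σΔπ) from
   observed totals, and blockwise exchange maps.
5. **Synthetic phantoms** — arterial + venous trees obeying Murray's law
   (d_parent^k = Σ d_child^k), bridged by capillaries and rasterized as
   capsules with known ground truth, so the entire pipeline is testable
   without any imaging data.

## Worked example

```python
import numpy as np
import lnvasc as lv
from lnvasc import imaging, starling
from lnvasc.hemodynamics import HemoParams, solve_network_flow, wall_shear_stress

# the wall-shear-stress convention behind whole-organ inflow boundary
# conditions: a 48.1 µm feeding arteriole carrying 0.22 µL/min of blood
# at 3 mPa·s experiences ~10 dyn/cm²
print(round(wall_shear_stress(0.22, 48.1, 3.0), 2))   # 10.07

# full pipeline on a synthetic phantom with known ground truth
spec = lv.PhantomSpec(branching_depth=3, root_artery_diameter=16,
                      root_vein_diameter=20, capillary_diameter_range=(9, 11),
                      domain_size=(420, 300, 300), voxel_size=2.0, random_seed=1)
truth = lv.generate_phantom(spec)
volume = lv.rasterize_graph(truth, spec)
mask = imaging.otsu_segment(imaging.median_filter_3(imaging.to_8bit(volume)))
graph = imaging.extract_graph(imaging.skeletonize(mask), mask,
    inlet_hint=truth.nodes[truth.inlet_node].position,
    outlet_hint=truth.nodes[truth.outlet_node].position)
lv.classify_vessels(graph)
print(len(graph.segments))                            # 10 vessels (truth: 10)

sol = solve_network_flow(graph, HemoParams(inflow=0.005))
print(round(sol.inlet_pressure, 2))                   # 12.19 mmHg
table, p_star = starling.sweep_lymph_pressure(
    graph, sol, lv.StarlingParams(), [0, 4, 10, 20, 30])
print(round(p_star, 2))                               # 4.67 mmHg
```

The numbers mean: the extracted vessel graph exactly recovers the phantom's
ten canonical vessels; with a 0.005 µL/min inflow the feeding arteriole sits
at 12.19 mmHg against the 10 mmHg venous outlet; and net transmural flow
through the vessel walls switches from blood→lymph to lymph→blood as the
lymph compartment pressure rises past 4.67 mmHg.

## Command line

```bash
lnvasc phantom --seed 0 --voxel-size 2.0 --out phantom_dir/
lnvasc segment --input phantom_dir/phantom.tiff --voxel-size 2.0 --out mask.tiff
lnvasc graph   --mask mask.tiff --voxel-size 2.0 --out graph_dir/
lnvasc flow    --graph-dir graph_dir/ --inflow 0.22 --outlet-pressure 10 --out flow.csv
lnvasc starling --graph-dir graph_dir/ --sweep 0:30:2 --out sweep.csv
lnvasc run     --config pipeline.yaml          # everything, with a report bundle
```

All stages read and write standard formats (TIFF stacks, GraphML/CSV graphs,
legacy-ASCII VTK PolyData for 3D viewers, CSV/JSON tables); every report
carries the SHA-256 hash of its configuration, and fixed seeds give
byte-identical outputs.

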