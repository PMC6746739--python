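# Methods

## Scope and model overview

`lnvasc` reconstructs and analyses the blood-vessel network of a whole small
organ (prototypically a murine popliteal lymph node) in three coupled but
sequential models:

1. a **geometric model**: the segmented vasculature is thinned to one-voxel
   centerlines and cut into *vessels* — centerline segments between branch
   or end points;
2. a **hemodynamic model**: steady laminar Poiseuille flow through the
   vessel graph treated as a resistor network;
3. an **exchange model**: Starling filtration across each vessel wall into a
   uniform lymph compartment.

The coupling is one-way: transmural losses are *not* subtracted from the
network flow. At physiological parameters the total transmural flow is a few
percent of the perfusing flow (tens of nL/min against hundreds), so the
feedback it would exert on the pressure field is below the other
uncertainties of the method; the approximation keeps the solve linear and
non-iterative.

## Image pipeline

Preprocessing follows the standard µCT workflow: linear 8-bit conversion,
a 3×3×3 median filter (reflect padding, i.e. edge-inclusive `symmetric`
reflection), optional user-supplied exclusion masks (a cone-mask helper
covers the classic pipette-tip crop), and Otsu thresholding on the 256-bin
histogram with plateau ties broken toward the lowest bin. Foreground is
*strictly above* the threshold.

Skeletonization uses homotopic 3D thinning (Lee's algorithm via
scikit-image), which preserves connected components and cycles. Skeleton
voxels with ≥3 26-neighbors are junction voxels (adjacent junction voxels are
merged into one node), voxels with exactly one neighbor are end nodes.
Terminal twigs shorter than 2 voxels are pruned before tracing — thinning of
thick vessels otherwise sheds spurs that would each count as a vessel
(configurable; disabled by `prune_spur_voxels=0`).

Vessel measurement conventions:

* **Length** — sum of exact Euclidean steps along the centerline
  (1, √2, √3 × voxel size). Thinning retracts the centerline by roughly one
  radius at free vessel ends, so lengths of stubby segments are biased short;
  at aspect ratios ≥ 10 the bias is within a few percent.
* **Volume** — every mask voxel is assigned to the vessel of its nearest
  centerline voxel (Euclidean distance transform), so vessel volumes
  partition the mask volume *exactly*.
* **Diameter** — volume-equivalent: A = V/L, d = 2√(A/π). At 0.81 µm voxels
  the voxel volume is 0.81³ ≈ 0.53 µm³.
* **Wall area** — two deliberately different estimators are exposed. The
  per-vessel lateral area S = π d L feeds the exchange model, which needs
  areas attributable to individual vessels. The blockwise marching-cubes
  isosurface area measures the network total including voxel-scale wall
  corrugation; the binary field is smoothed with a σ = 0.6 voxel Gaussian
  before triangulation because raw 0/1 marching cubes inherits the voxel
  staircase and overestimates curved areas by ~15–25%, while flat faces and
  vessels down to ~4 voxels across stay essentially unbiased at this σ.
  Blocks share one voxel plane with their neighbours, so the block
  decomposition retiles exactly the whole-volume marching-cubes cells: no
  internal cut faces arise and the blockwise total equals the whole-volume
  area up to triangulation noise (<2%).

Coordinates are voxel-center: physical position = index × voxel size, 0-based
indices, isotropic voxels only (anisotropy is rejected explicitly).

## Hemodynamics

Each vessel is a resistor R = 128 µ_app L/(π d⁴). The apparent viscosity is
the empirical in-vivo diameter/hematocrit law

    µ45(d) = 6 e^(−0.085d) + 3.2 − 2.44 e^(−0.06 d^0.645)
    C(d)   = (0.8 + e^(−0.075d))(−1 + 1/(1+10⁻¹¹d¹²)) + 1/(1+10⁻¹¹d¹²)
    µ_rel  = [1 + (µ45−1)·((1−H_D)^C −1)/((1−0.45)^C −1)·(d/(d−1.1))²]·(d/(d−1.1))²

(d in µm), multiplied by a plasma viscosity of 1.2 mPa·s (default). The law
is singular at d = 1.1 µm; diameters below 3 µm (default clamp) are clamped
with a warning before evaluation — vessels that small are below the reliable
resolution of the imaging anyway. Discharge hematocrit defaults to H_D = 0.45
and is **uniform**: no phase separation at bifurcations, which keeps the
system linear. A constant-viscosity ("Newtonian") variant is available as a
configuration switch for sensitivity checks.

Boundary conditions follow the whole-organ convention: fixed inflow through
the feeding arteriole (default 0.22 µL/min; the helper
`inflow_for_wall_shear_stress` inverts τ = 32µQ/(πd³) to pick an inflow
giving a physiological ~10 dyn/cm² at the feeding arteriole), fixed pressure
at the main draining vein (default 10 mmHg), and zero flow at all other end
points (vessels truncated at the imaging boundary). Node pressures solve the
sparse conductance Laplacian (nodal analysis, `scipy.sparse.linalg.spsolve`);
the residual of the conservation equations is checked against 10⁻⁸ × inflow.
Per-vessel pressure is the mean of its endpoint node pressures. Internal
units are µm / mmHg / µL·min⁻¹ / mPa·s with all conversions centralized in
`lnvasc.units` (1 mmHg = 133.322 Pa, 1 µL/min = 10⁻⁹/60 m³/s,
1 Pa = 10 dyn/cm²).

## Classification

Arteries (veins) are vessels within ten branching generations of the feeding
arteriole (draining vein) that exceed 10 µm in diameter; everything else —
including large vessels deeper than ten generations — is a capillary. The
generation of a vessel is the *minimum* number of branch nodes traversed on
any path from the respective root, computed by 0–1 breadth-first search;
this extends the tree-oriented rule to the loopy capillary bed without
changing its value on trees. A vessel qualifying from both sides goes to the
nearer side, artery on an exact tie (configurable convention). Vessels
unreachable from inlet or outlet stay `unclassified` and are reported.

## Starling exchange

Per vessel, J = Lp·S·[(P_lymph − P_b) − σ(π_lymph − π_blood)], positive for
lymph→blood, with S = πdL and P_b the vessel's mean blood pressure. Lymph
hydrostatic and oncotic pressures are uniform over the organ. The total is
affine in P_lymph with slope Lp·ΣS; the zero-net-flow pressure has the
closed form P* = (ΣSᵢP_b,ᵢ)/(ΣSᵢ) + σ(π_lymph − π_blood), which is checked
against numeric root-finding in the tests.

**Parameter conventions, not measurements**: defaults ship as σ = 0.9,
π_blood = 25 mmHg, π_lymph = 18 mmHg (effective oncotic term σΔπ = 6.3 mmHg)
and Lp = 0.042 µm·min⁻¹·mmHg⁻¹. The Lp value is calibrated so that a network
with ~1.5×10⁷ µm² of wall area — the scale of a whole popliteal node — has a
sweep slope of ~0.625 nL·min⁻¹·mmHg⁻¹, the slope implied by whole-node
transmural totals reported in the literature (0 nL/min near P_lymph = 4 mmHg
and ~10 nL/min at 20 mmHg). Since P* depends only on the pressure field and
σΔπ, and the slope only on Lp·ΣS, `calibrate_starling` can recover both from
any two observed (P_lymph, ΣJ) pairs; with three or more it reports
least-squares residuals, which are nonzero for published rounded triples.

## Synthetic phantoms

The generator emulates the *structural* features the pipeline relies on:
a bifurcating arterial tree and venous tree whose child diameters satisfy
Murray's law d_parent^k = Σ d_child^k exactly (k = 3 default, symmetric
splits), joined through capillary bridges (nearest-terminal matching without
replacement; densities above one add random extra bridges, producing the
loops real capillary beds have), rasterized as capsules — a voxel is
foreground iff its center lies inside a cylinder-with-hemispherical-caps of
the vessel's diameter — with optional Gaussian intensity noise. Geometry
defaults (length/diameter ratio 2.5, branch angle 45°, trees rooted at
opposite faces) keep the two trees in disjoint halves of the domain and keep
the medial-axis junction of rasterized bifurcations within ~1.5 voxels of
the polyline junction, so ground-truth comparisons are meaningful. Segments
are straight; real vessels are tortuous, but ground-truth testability favors
simple geometry.

A terminal tip that carries exactly one capillary has degree 2 and is
therefore *not* a branch or end point; `VesselGraph.merge_degree2_nodes()`
produces the canonical vessel-definition view (merged L, V, and
volume-equivalent d) used as ground truth in round-trip tests.

What passing the phantom tests does **not** show: robustness to casting
artefacts (bubbles, breaks), tortuosity, contact between unrelated vessels,
anisotropic resolution, or realistic capillary anastomosis statistics. The
phantom validates the measurement chain, not the biology.

## Problem sizes and numerical choices

The bundled reference phantom used by tests and `scripts/acceptance.py` is a
depth-3 arterio-venous pair (10 canonical vessels) rasterized at 2 µm voxels
into a 210×150×150 grid — large enough that every vessel is ≥ 4 voxels
across and every stage (including marching cubes and the distance-transform
voxel partition) runs in seconds. Whole-node stacks (~2500³ voxels at
0.81 µm) run through the identical code path; only memory and patience
differ.

Other conventions: Otsu ties → lowest bin; 26-connectivity throughout the
skeleton; marching cubes at iso-level 0.5; block maps apportion per-vessel
quantities by *exact* analytic splitting of centerline polylines at block
boundaries, so block totals conserve network totals to machine precision;
the reference organ volume for density/fraction denominators defaults to the
convex hull of the vascular foreground (a proxy for the organ envelope when
no tissue segmentation exists) and accepts a user override; degenerate hulls
report zero volume with a warning.

## Known limitations

* One-way hemodynamics↔exchange coupling (see above).
* Uniform hematocrit; no plasma skimming.
* Centerline placement differs from proprietary skeletonization tools;
  agreement is validated against phantom ground truth, not voxel-exact
  against any particular software.
* Vessel lengths at free ends are biased short by about one radius.
* The classification rule inherits the 10-generation / 10 µm thresholds; on
  networks whose feeding vessels are truncated differently the class
  fractions shift accordingly.
* Starling defaults are calibrated conventions; absolute transmural flows
  scale linearly with the configured Lp.
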