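# Example full-pipeline configuration (phantom input).
# For real data replace the `phantom:` block with `input_tiff: path/to/stack.tiff`
# and set voxel_size to the scan's effective pixel size in µm (e.g. 0.81).
voxel_size: 2.0
phantom:
  branching_depth: 3
  root_artery_diameter: 16.0
  root_vein_diameter: 20.0
  capillary_diameter_range: [9.0, 11.0]
  domain_size: [420.0, 300.0, 300.0]
block_sizes: [80, 100]        # voxels per block edge for the spatial maps
hemo:
  inflow: 0.22                # µL/min through the feeding arteriole
  outlet_pressure: 10.0       # mmHg at the main draining vein
  hematocrit: 0.45
  plasma_viscosity: 1.2       # mPa·s
starling:
  Lp: 0.042                   # µm·min⁻¹·mmHg⁻¹ (calibrated default)
  sigma: 0.9
  pi_blood: 25.0              # mmHg
  pi_lymph: 18.0              # mmHg
lymph_pressure_sweep: [0.0, 4.0, 10.0, 20.0, 30.0]
output_dir: lnvasc_out
seed: 0
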