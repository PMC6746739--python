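"""Unit conventions and conversion constants.

The internal unit system is the one natural at microvascular scale:

======================  =========
quantity                unit
======================  =========
length, diameter        µm
pressure                mmHg
volumetric blood flow   µL/min
transmural flux         nL/min
viscosity               mPa·s
velocity                mm/s
wall shear stress       dyn/cm²
======================  =========

All conversions to and from SI happen through the constants below so that
no magic numbers appear inside the physics.
"""

# pressure
PA_PER_MMHG = 133.322

# flow
M3_PER_S_PER_UL_PER_MIN = 1e-9 / 60.0  # 1 µL/min in m³/s

# length
M_PER_UM = 1e-6

# viscosity
PA_S_PER_MPA_S = 1e-3

# stress
DYN_PER_CM2_PER_PA = 10.0

# volumes
UM3_PER_NL = 1e6
UM3_PER_MM3 = 1e9
UM2_PER_MM2 = 1e6
UM_PER_CM = 1e4
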