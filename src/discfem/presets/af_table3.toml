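# Annulus fibrosus parameter set identified by inverse FEM against averaged
# cadaveric range-of-motion curves (flexion, extension, lateral bending,
# axial rotation) of non-degenerated segments.
[material]
kind = "AF"
c10_mpa = 0.016
c01_mpa = 0.001
a1_mpa = 1.0
a2 = 151.0
k_mpa = 170.0
rho0_kg_m3 = 1000.0
phi_deg = 30.0
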