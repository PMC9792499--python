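# Annulus fibrosus: Mooney-Rivlin matrix + two exponential collagen fiber
# families at +/-30 degrees. Bulk modulus corresponds to a Poisson ratio of 0.45.
[material]
kind = "AF"
c10_mpa = 0.18
c01_mpa = 0.045
a1_mpa = 2.0
a2 = 100.0
k_mpa = 4.35
rho0_kg_m3 = 1000.0
phi_deg = 30.0
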