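# Nucleus pulposus: compressible Mooney-Rivlin.
# Bulk modulus corresponds to a Poisson ratio of 0.495.
[material]
kind = "NP"
b10_mpa = 0.12
b01_mpa = 0.03
k_mpa = 29.9
rho0_kg_m3 = 1000.0
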