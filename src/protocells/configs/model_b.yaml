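# Scenario (b): no information drift, large mutation scale
d: 500
L: 25
k0: 0.1
gamma0: 0.01
s: 1
b_eta: 1
a_zeta: 0
b_zeta: 1
eps_eta: 0.01
eps_zeta: 0.01
g: 0.002
f: 1000
z: 1.0e-5
rho0: 1000000000000000000
U00: 1000
T_max: 200000
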