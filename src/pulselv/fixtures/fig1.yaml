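# Deterministic level curves: equilibrium and three closed orbits
eps: 0.1
a: 0.9
b: 1.0
c: 0.5
f: 0.5
eps2_s: 0.2
eps2_gamma: 0.2
levels: [0.892, 1.146, 1.565]
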