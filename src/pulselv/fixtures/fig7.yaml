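# Self-competition sweep: relative fluctuations for eps^2 s in 0.08..0.15
eps: 0.1
a: 0.9
b: 1.0
c: 0.5
f: 0.5
eps2_s: 0.08
eps2_gamma: 0.1
lambda1: 1.0
lambda2: 1.0
eps2_EY2_1: 0.015
eps2_EY2_2: 0.015
sweep:
  parameter: eps2_s
  values: [0.08, 0.10, 0.12, 0.15]
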