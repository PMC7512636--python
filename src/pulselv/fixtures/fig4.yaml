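# Time-delay sweep: stationary PDFs for eps^2 gamma in 0.05..0.12
eps: 0.1
a: 0.9
b: 1.0
c: 0.5
f: 0.5
eps2_s: 0.2
eps2_gamma: 0.05
lambda1: 1.0
lambda2: 1.0
intensity_1: 0.015
intensity_2: 0.015
sweep:
  parameter: eps2_gamma
  values: [0.05, 0.08, 0.10, 0.12]
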