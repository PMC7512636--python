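# Amplitude-variance sweep at fixed lambda = 0.8
eps: 0.1
a: 0.9
b: 1.0
c: 0.5
f: 0.5
eps2_s: 0.2
eps2_gamma: 0.1
lambda1: 0.8
lambda2: 0.8
eps2_EY2_1: 0.01
eps2_EY2_2: 0.01
sweep:
  parameter: eps2_EY2
  values: [0.005, 0.01, 0.015, 0.02]
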