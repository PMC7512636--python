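# Stationary PDFs at lower noise intensity
eps: 0.1
a: 0.9
b: 1.0
c: 0.5
f: 0.5
eps2_s: 0.2
eps2_gamma: 0.1
lambda1: 0.4
lambda2: 0.4
intensity_1: 0.0075
intensity_2: 0.0075
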