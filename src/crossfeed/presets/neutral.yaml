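# Fully symmetric control parameter set (normalized units, K = 1)
r1: 1.0
r2: 1.0
kcA: 1.0
kcL: 1.0
beta1: 0.1
beta2: 0.1
gamma1: 1.0
gamma2: 1.0
K: 1.0
ro: 0.0
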