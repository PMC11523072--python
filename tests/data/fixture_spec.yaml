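# frozen synthetic-macrocycle spec used for regression tests
seed: 42
ring_size: 15
n_tail: 3
n_methyl: 1
n_prochiral: 2
state_fractions: [0.973, 0.027]
jitter_sigma: 0.01
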