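cluster	parent	child	k
synn0m0_A	n0_0	n1_1	1
synn0m0_A	n1_1	n2_2	1
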