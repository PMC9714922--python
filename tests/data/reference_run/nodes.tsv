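cluster	node_id	K	signature	members
synn0m0_A	n0_0	0		synn0m0_A,synn0m1_A
synn0m0_A	n1_1	1	synn1m0_B	synn1m0_A,synn1m1_A
synn0m0_A	n2_2	2	synn1m0_B,synn2m0_C	synn2m0_A,synn2m1_A
synn1m0_B	n1_0	1	synn0m0_A	synn1m0_B,synn1m1_B,synn2m0_B,synn2m1_B
synn2m0_C	n1_0	1	synn0m0_A	synn2m0_C,synn2m1_C
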