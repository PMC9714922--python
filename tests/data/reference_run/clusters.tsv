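representative_id	member_id	identity_pct
synn0m0_A	synn0m0_A	100.00
synn0m0_A	synn0m1_A	100.00
synn0m0_A	synn1m0_A	100.00
synn0m0_A	synn1m1_A	100.00
synn0m0_A	synn2m0_A	100.00
synn0m0_A	synn2m1_A	100.00
synn1m0_B	synn1m0_B	100.00
synn1m0_B	synn1m1_B	100.00
synn1m0_B	synn2m0_B	100.00
synn1m0_B	synn2m1_B	100.00
synn2m0_C	synn2m0_C	100.00
synn2m0_C	synn2m1_C	100.00
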