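cluster	parent_node	child_node	test	restriction	K	plus_k	TP	FP	FN	TN	Sen	Spe	Acc	PPV	NPV	Sen_r	Spe_r	Acc_r	PPV_r	NPV_r
synn0m0_A	n0_0	n1_1	edge	C_all	0	1	5	8	1	42	0.833333	0.840000	0.839286	0.384615	0.976744	0.232143	0.767857	0.710459	0.107143	0.892857
synn0m0_A	n0_0	n1_1	edge	C_minus_IR	0	1	5	8	1	42	0.833333	0.840000	0.839286	0.384615	0.976744	0.232143	0.767857	0.710459	0.107143	0.892857
synn0m0_A	n0_0	n1_1	edge	S_all	0	1	4	5	1	42	0.800000	0.893617	0.884615	0.444444	0.976744	0.173077	0.826923	0.764053	0.096154	0.903846
synn0m0_A	n0_0	n1_1	edge	S_minus_IR	0	1	4	5	1	42	0.800000	0.893617	0.884615	0.444444	0.976744	0.173077	0.826923	0.764053	0.096154	0.903846
synn0m0_A	n0_0		k_shell	C_all	0	1	5	8	1	42	0.833333	0.840000	0.839286	0.384615	0.976744	0.232143	0.767857	0.710459	0.107143	0.892857
synn0m0_A	n0_0		k_shell	C_minus_IR	0	1	5	8	1	42	0.833333	0.840000	0.839286	0.384615	0.976744	0.232143	0.767857	0.710459	0.107143	0.892857
synn0m0_A	n0_0		k_shell	S_all	0	1	4	5	1	42	0.800000	0.893617	0.884615	0.444444	0.976744	0.173077	0.826923	0.764053	0.096154	0.903846
synn0m0_A	n0_0		k_shell	S_minus_IR	0	1	4	5	1	42	0.800000	0.893617	0.884615	0.444444	0.976744	0.173077	0.826923	0.764053	0.096154	0.903846
synn0m0_A	n0_0		k_shell	C_all	0	2	6	7	6	41	0.500000	0.854167	0.783333	0.461538	0.872340	0.216667	0.783333	0.670000	0.200000	0.800000
synn0m0_A	n0_0		k_shell	C_minus_IR	0	2	6	7	6	41	0.500000	0.854167	0.783333	0.461538	0.872340	0.216667	0.783333	0.670000	0.200000	0.800000
synn0m0_A	n0_0		k_shell	S_all	0	2	5	4	6	41	0.454545	0.911111	0.821429	0.555556	0.872340	0.160714	0.839286	0.705995	0.196429	0.803571
synn0m0_A	n0_0		k_shell	S_minus_IR	0	2	5	4	6	41	0.454545	0.911111	0.821429	0.555556	0.872340	0.160714	0.839286	0.705995	0.196429	0.803571
synn0m0_A	n0_0		all_shell	C_all	0	2	6	7	6	41	0.500000	0.854167	0.783333	0.461538	0.872340	0.216667	0.783333	0.670000	0.200000	0.800000
synn0m0_A	n0_0		all_shell	C_minus_IR	0	2	6	7	6	41	0.500000	0.854167	0.783333	0.461538	0.872340	0.216667	0.783333	0.670000	0.200000	0.800000
synn0m0_A	n0_0		all_shell	S_all	0	2	5	4	6	41	0.454545	0.911111	0.821429	0.555556	0.872340	0.160714	0.839286	0.705995	0.196429	0.803571
synn0m0_A	n0_0		all_shell	S_minus_IR	0	2	5	4	6	41	0.454545	0.911111	0.821429	0.555556	0.872340	0.160714	0.839286	0.705995	0.196429	0.803571
synn0m0_A	n1_1	n2_2	edge	C_all	1	1	5	7	1	43	0.833333	0.860000	0.857143	0.416667	0.977273	0.214286	0.785714	0.724490	0.107143	0.892857
synn0m0_A	n1_1	n2_2	edge	C_minus_IR	1	1	5	7	1	37	0.833333	0.840909	0.840000	0.416667	0.973684	0.240000	0.760000	0.697600	0.120000	0.880000
synn0m0_A	n1_1	n2_2	edge	S_all	1	1	3	5	1	43	0.750000	0.895833	0.884615	0.375000	0.977273	0.153846	0.846154	0.792899	0.076923	0.923077
synn0m0_A	n1_1	n2_2	edge	S_minus_IR	1	1	3	5	1	37	0.750000	0.880952	0.869565	0.375000	0.973684	0.173913	0.826087	0.769376	0.086957	0.913043
synn0m0_A	n1_1		k_shell	C_all	1	1	5	7	1	43	0.833333	0.860000	0.857143	0.416667	0.977273	0.214286	0.785714	0.724490	0.107143	0.892857
synn0m0_A	n1_1		k_shell	C_minus_IR	1	1	5	7	1	37	0.833333	0.840909	0.840000	0.416667	0.973684	0.240000	0.760000	0.697600	0.120000	0.880000
synn0m0_A	n1_1		k_shell	S_all	1	1	3	5	1	43	0.750000	0.895833	0.884615	0.375000	0.977273	0.153846	0.846154	0.792899	0.076923	0.923077
synn0m0_A	n1_1		k_shell	S_minus_IR	1	1	3	5	1	37	0.750000	0.880952	0.869565	0.375000	0.973684	0.173913	0.826087	0.769376	0.086957	0.913043
synn0m0_A	n1_1		all_shell	C_all	1	1	5	7	1	43	0.833333	0.860000	0.857143	0.416667	0.977273	0.214286	0.785714	0.724490	0.107143	0.892857
synn0m0_A	n1_1		all_shell	C_minus_IR	1	1	5	7	1	37	0.833333	0.840909	0.840000	0.416667	0.973684	0.240000	0.760000	0.697600	0.120000	0.880000
synn0m0_A	n1_1		all_shell	S_all	1	1	3	5	1	43	0.750000	0.895833	0.884615	0.375000	0.977273	0.153846	0.846154	0.792899	0.076923	0.923077
synn0m0_A	n1_1		all_shell	S_minus_IR	1	1	3	5	1	37	0.750000	0.880952	0.869565	0.375000	0.973684	0.173913	0.826087	0.769376	0.086957	0.913043
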