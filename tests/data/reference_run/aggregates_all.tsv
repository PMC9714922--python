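n	Sen	Spe	Acc	PPV	NPV	Sen_r	Spe_r	Acc_r	PPV_r	NPV_r	Sen_over_1mSpe	PPV_over_1mNPV	Sen_ci_low	Sen_ci_high
28	0.708983	0.872452	0.845308	0.433379	0.946372	0.195591	0.804409	0.726969	0.127570	0.872430	5.684050	13.186302	0.665038	0.753160
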