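signature	dataset	pct_positive	sensitivity	specificity
Huh7-R-A7	GSE14323	53.9	0.56	1.0
Huh7-R-A7	GSE14520_GPL571	55.8	0.53	0.67
Huh7-R-A7	GSE14520_GPL3921	44.5	0.47	0.70
Huh7-R-A7	GSE45267	50.6	0.43	0.69
Huh7-R-A7	GSE62232	58.2	0.42	1.0
Huh7-R-A7	GSE6764	53.3	0.61	0.86
HepG2-R	GSE14323	32.2	0.42	0.93
HepG2-R	GSE14520_GPL571	20.9	0.54	0.88
HepG2-R	GSE14520_GPL3921	22.5	0.53	0.90
HepG2-R	GSE45267	24.1	0.57	0.97
HepG2-R	GSE62232	27.5	0.42	1.0
HepG2-R	GSE6764	30.7	0.68	0.67
HCC-3sp-R	GSE14323	31.0	0.45	1.0
HCC-3sp-R	GSE14520_GPL571	23.3	0.50	0.87
HCC-3sp-R	GSE14520_GPL3921	25.6	0.46	0.83
HCC-3sp-R	GSE45267	31.0	0.49	0.79
HCC-3sp-R	GSE62232	28.6	0.40	1.0
HCC-3sp-R	GSE6764	26.7	0.57	0.86
Xeno-R	GSE14323	25.2	0.33	0.0
Xeno-R	GSE14520_GPL571	60.5	0.82	1.0
Xeno-R	GSE14520_GPL3921	50.1	0.86	0.99
Xeno-R	GSE45267	62.1	0.86	1.0
Xeno-R	GSE62232	40.7	0.60	1.0
Xeno-R	GSE6764	40.0	0.93	0.80
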