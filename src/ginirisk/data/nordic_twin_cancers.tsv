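site	h2_percent	env2_percent	lifetime_risk_percent	lambda_m
Overall cancer	33.0	0.0	32.4	1.4
Head and neck	9.0	26.0	0.8	7.5
Stomach	22.0	6.0	1.1	6.2
Colon	15.0	16.0	2.9	3.8
Rectum and anus	14.0	10.0	1.9	3.5
Lung	18.0	24.0	3.2	5.5
Melanoma	58.0	0.0	1.2	16.3
Non-Melanoma	43.0	0.0	1.9	7.6
Breast	31.0	16.0	9.4	3.0
Corpus uteri	27.0	0.0	2.0	3.5
Ovary	39.0	0.0	1.6	5.4
Prostate	57.0	0.0	10.5	3.6
Testis	37.0	24.0	0.5	27.6
Kidney	38.0	0.0	0.8	8.4
Bladder, other urinary organs	30.0	0.0	2.2	4.5
Leukemia, other	57.0	0.0	0.6	25.3
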