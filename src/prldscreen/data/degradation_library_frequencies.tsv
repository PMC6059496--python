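# Published per-residue frequencies for the constitutive ADE+ (selected) vs naive ade-
# (reference) libraries of the hnRNPA2-Sup35 and hnRNPA1-Sup35 mutagenesis screens,
# with the printed ln odds ratios (degradation propensity scores, DP_aa) and p-values.
# Frequencies are printed to 3 decimals; ln(OR) columns are the published values.
context	residue	is_group	f_sel	f_ref	ln_or_printed	p_printed
A2	V	0	0.078	0.023	1.30	7.8e-4
A2	M	0	0.041	0.013	1.21	0.024
A2	L	0	0.125	0.045	1.11	1.7e-4
A2	I	0	0.047	0.020	0.89	0.049
A2	Y	0	0.057	0.040	0.38	0.29
A2	A	0	0.051	0.040	0.25	0.58
A2	F	0	0.047	0.040	0.18	0.71
A2	P	0	0.057	0.053	0.10	0.87
A2	T	0	0.057	0.055	0.046	1.00
A2	S	0	0.128	0.125	0.031	0.91
A2	W	0	0.024	0.025	-0.057	1.00
A2	D	0	0.041	0.053	-0.27	0.59
A2	G	0	0.068	0.088	-0.28	0.39
A2	H	0	0.034	0.045	-0.30	0.56
A2	K	0	0.020	0.028	-0.31	0.63
A2	C	0	0.030	0.050	-0.52	0.25
A2	R	0	0.054	0.110	-0.77	9.4e-3
A2	E	0	0.014	0.030	-0.81	0.20
A2	Q	0	0.014	0.035	-0.97	0.093
A2	N	0	0.014	0.085	-1.91	1.5e-5
A2	Aromatic	1	0.128	0.105	0.23	0.34
A2	Charged	1	0.128	0.220	-0.65	2.0e-3
A2	Hydrophobic	1	0.291	0.100	1.30	1.7e-10
A2	Polar	1	0.287	0.313	-0.12	0.50
A2	QN	1	0.027	0.120	-1.59	3.8e-6
A1	V	0	0.083	0.042	0.74	0.049
A1	M	0	0.033	0.011	1.12	0.074
A1	L	0	0.100	0.042	0.94	6.3e-3
A1	I	0	0.083	0.033	0.97	9.2e-3
A1	Y	0	0.038	0.031	0.21	0.65
A1	A	0	0.038	0.036	0.039	1.00
A1	F	0	0.067	0.042	0.50	0.19
A1	P	0	0.063	0.064	-0.023	1.00
A1	T	0	0.054	0.061	-0.13	0.86
A1	S	0	0.125	0.119	0.052	0.90
A1	W	0	0.033	0.025	0.30	0.62
A1	D	0	0.021	0.047	-0.85	0.12
A1	G	0	0.033	0.075	-0.85	0.034
A1	H	0	0.050	0.042	0.19	0.69
A1	K	0	0.004	0.033	-2.11	0.019
A1	C	0	0.063	0.036	0.58	0.17
A1	R	0	0.058	0.125	-0.84	7.6e-3
A1	E	0	0.017	0.019	-0.16	1.00
A1	Q	0	0.017	0.039	-0.87	0.15
A1	N	0	0.021	0.078	-1.38	2.9e-3
A1	Aromatic	1	0.138	0.097	0.39	0.15
A1	Charged	1	0.100	0.225	-0.96	6.9e-5
A1	Hydrophobic	1	0.300	0.128	1.07	3.5e-7
A1	Polar	1	0.263	0.297	-0.17	0.41
A1	QN	1	0.038	0.117	-1.22	5.1e-4
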