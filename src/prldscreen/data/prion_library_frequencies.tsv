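# Published per-residue frequencies for the [PRION+] (selected) vs naive ade-
# (reference) libraries of the hnRNPA2-Sup35 and hnRNPA1-Sup35 mutagenesis screens,
# with the printed ln odds ratios (prion propensity scores, PP_aa) and p-values.
context	residue	is_group	f_sel	f_ref	ln_or_printed	p_printed
A2	F	0	0.093	0.040	0.90	0.011
A2	Y	0	0.088	0.040	0.84	0.018
A2	W	0	0.037	0.025	0.41	0.45
A2	T	0	0.079	0.055	0.38	0.30
A2	V	0	0.032	0.023	0.38	0.44
A2	I	0	0.028	0.020	0.34	0.58
A2	A	0	0.051	0.040	0.25	0.54
A2	P	0	0.060	0.053	0.14	0.71
A2	M	0	0.014	0.013	0.11	1.00
A2	H	0	0.046	0.045	0.030	1.00
A2	G	0	0.083	0.088	-0.053	1.00
A2	E	0	0.028	0.030	-0.079	1.00
A2	L	0	0.042	0.045	-0.080	1.00
A2	R	0	0.093	0.110	-0.19	0.58
A2	S	0	0.093	0.125	-0.34	0.29
A2	Q	0	0.023	0.035	-0.43	0.47
A2	C	0	0.032	0.050	-0.45	0.41
A2	D	0	0.032	0.053	-0.50	0.31
A2	N	0	0.037	0.085	-0.88	0.029
A2	K	0	0.009	0.028	-1.11	0.15
A2	Aromatic	1	0.218	0.105	0.86	2.7e-4
A2	Charged	1	0.162	0.220	-0.38	0.092
A2	Hydrophobic	1	0.116	0.100	0.16	0.58
A2	Polar	1	0.301	0.313	-0.054	0.78
A2	QN	1	0.060	0.120	-0.76	0.017
A1	F	0	0.069	0.042	0.53	0.13
A1	Y	0	0.069	0.031	0.86	0.028
A1	W	0	0.020	0.025	-0.24	0.80
A1	T	0	0.049	0.061	-0.23	0.61
A1	V	0	0.053	0.042	0.25	0.58
A1	I	0	0.026	0.033	-0.24	0.65
A1	A	0	0.036	0.036	0.0021	1.00
A1	P	0	0.026	0.064	-0.93	0.026
A1	M	0	0.030	0.011	1.00	0.10
A1	H	0	0.056	0.042	0.31	0.47
A1	G	0	0.049	0.075	-0.45	0.20
A1	E	0	0.007	0.019	-1.10	0.19
A1	L	0	0.053	0.042	0.25	0.58
A1	R	0	0.092	0.125	-0.34	0.21
A1	S	0	0.145	0.119	0.22	0.36
A1	Q	0	0.023	0.039	-0.54	0.27
A1	C	0	0.039	0.036	0.093	0.84
A1	D	0	0.033	0.047	-0.38	0.43
A1	N	0	0.109	0.078	0.37	0.18
A1	K	0	0.016	0.033	-0.72	0.22
A1	Aromatic	1	0.158	0.097	0.55	0.025
A1	Charged	1	0.148	0.225	-0.51	0.013
A1	Hydrophobic	1	0.161	0.128	0.27	0.22
A1	Polar	1	0.299	0.297	0.010	1.00
A1	QN	1	0.132	0.117	0.14	0.64
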