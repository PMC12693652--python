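set	variant	complex_id	m0	m1	m2	m3	m4	printed_lo	printed_hi
wt	WT	PMCA1a	0.71	0.68	0.67	0.65	0.65	0.64	0.7
wt	WT	PMCA1b	0.71	0.73	0.68	0.66	0.61	0.62	0.74
wt	WT	PMCA2a_2b_3b	0.73	0.67	0.69	0.63	0.62	0.61	0.72
wt	WT	PMCA2c_2d	0.59	0.53	0.54	0.55	0.53	0.52	0.58
wt	WT	PMCA3a	0.64	0.62	0.58	0.55	0.55	0.54	0.64
wt	WT	PMCA4a_4c	0.64	0.61	0.59	0.59	0.56	0.56	0.63
wt	WT	PMCA4b	0.74	0.65	0.65	0.62	0.59	0.58	0.72
literature	V1143F	PMCA2b	0.69	0.71	0.70	0.60	0.62	0.6	0.73
literature	W1104A	PMCA3b	0.66	0.63	0.59	0.61	0.55	0.56	0.66
literature	G1107D	PMCA3b	0.71	0.69	0.71	0.71	0.68	0.68	0.72
substitution	L5R	PMCA1a	0.69	0.67	0.66	0.67	0.62	0.63	0.69
substitution	L5R	PMCA1b	0.73	0.66	0.68	0.66	0.61	0.61	0.72
substitution	L5R	PMCA2a_2b_3b	0.8	0.7	0.68	0.68	0.68	0.64	0.77
substitution	L5R	PMCA2c_2d	0.62	0.59	0.6	0.55	0.57	0.55	0.62
substitution	L5R	PMCA3a	0.68	0.55	0.61	0.56	0.58	0.53	0.66
substitution	L5R	PMCA4a_4c	0.67	0.62	0.63	0.6	0.41	0.46	0.71
substitution	L5R	PMCA4b	0.67	0.64	0.65	0.64	0.62	0.62	0.67
substitution	N6I	PMCA1a	0.71	0.71	0.63	0.63	0.6	0.59	0.72
substitution	N6I	PMCA1b	0.68	0.65	0.63	0.65	0.61	0.61	0.68
substitution	N6I	PMCA2a_2b_3b	0.68	0.62	0.61	0.57	0.58	0.56	0.67
substitution	N6I	PMCA2c_2d	0.65	0.62	0.57	0.57	0.4	0.44	0.68
substitution	N6I	PMCA3a	0.65	0.6	0.63	0.61	0.35	0.41	0.72
substitution	N6I	PMCA4a_4c	0.57	0.61	0.55	0.58	0.53	0.53	0.61
substitution	N6I	PMCA4b	0.7	0.59	0.56	0.56	0.54	0.51	0.67
substitution	I8T	PMCA1a	0.82	0.73	0.73	0.68	0.62	0.62	0.81
substitution	I8T	PMCA1b	0.79	0.72	0.72	0.7	0.74	0.69	0.78
substitution	I8T	PMCA2a_2b_3b	0.75	0.74	0.72	0.68	0.43	0.5	0.83
substitution	I8T	PMCA2c_2d	0.63	0.63	0.63	0.63	0.58	0.59	0.65
substitution	I8T	PMCA3a	0.67	0.66	0.65	0.65	0.64	0.64	0.67
substitution	I8T	PMCA4a_4c	0.69	0.67	0.62	0.62	0.6	0.59	0.69
substitution	I8T	PMCA4b	0.7	0.63	0.61	0.58	0.62	0.57	0.68
substitution	V14E/D	PMCA1a	0.6	0.59	0.6	0.58	0.54	0.55	0.61
substitution	V14E/D	PMCA1b	0.62	0.54	0.54	0.56	0.4	0.43	0.63
substitution	V14E/D	PMCA2a_2b_3b	0.61	0.59	0.57	0.55	0.56	0.55	0.61
substitution	V14E/D	PMCA2c_2d	0.56	0.56	0.52	0.39	0.38	0.37	0.59
substitution	V14E/D	PMCA3a	0.59	0.56	0.54	0.55	0.52	0.52	0.58
substitution	V14E/D	PMCA4a_4c	0.53	0.53	0.42	0.35	0.37	0.33	0.55
substitution	V14E/D	PMCA4b	0.54	0.53	0.51	0.49	0.41	0.43	0.56
substitution	F18S	PMCA1a	0.69	0.69	0.64	0.62	0.59	0.59	0.7
substitution	F18S	PMCA1b	0.71	0.72	0.69	0.67	0.61	0.63	0.73
substitution	F18S	PMCA2a_2b_3b	0.64	0.64	0.6	0.43	0.42	0.41	0.68
substitution	F18S	PMCA2c_2d	0.68	0.6	0.59	0.63	0.6	0.57	0.67
substitution	F18S	PMCA3a	0.65	0.61	0.6	0.59	0.58	0.57	0.64
substitution	F18S	PMCA4a_4c	0.66	0.61	0.61	0.6	0.4	0.45	0.7
substitution	F18S	PMCA4b	0.58	0.6	0.57	0.47	0.45	0.45	0.62
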