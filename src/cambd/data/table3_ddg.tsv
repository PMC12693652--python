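set	complex_id	substitution	method	ddg
evaluated	PMCA1a	L5R	foldx	-3.92
evaluated	PMCA1a	N6I	foldx	-0.72
evaluated	PMCA1a	I8T	foldx	-4.14
evaluated	PMCA1a	V14E/D	foldx	3.42
evaluated	PMCA1a	F18S	foldx	1.17
evaluated	PMCA1b	L5R	foldx	-0.69
evaluated	PMCA1b	N6I	foldx	-4.97
evaluated	PMCA1b	I8T	foldx	5.82
evaluated	PMCA1b	V14E/D	foldx	3.15
evaluated	PMCA1b	F18S	foldx	5.64
evaluated	PMCA2a_2b_3b	L5R	foldx	8.01
evaluated	PMCA2a_2b_3b	N6I	foldx	2.91
evaluated	PMCA2a_2b_3b	I8T	foldx	7.09
evaluated	PMCA2a_2b_3b	V14E/D	foldx	7.29
evaluated	PMCA2a_2b_3b	F18S	foldx	6.59
evaluated	PMCA2c_2d	L5R	foldx	0.22
evaluated	PMCA2c_2d	N6I	foldx	-8.28
evaluated	PMCA2c_2d	I8T	foldx	2.21
evaluated	PMCA2c_2d	V14E/D	foldx	9.19
evaluated	PMCA2c_2d	F18S	foldx	4.99
evaluated	PMCA3a	L5R	foldx	3.11
evaluated	PMCA3a	N6I	foldx	1.15
evaluated	PMCA3a	I8T	foldx	4.59
evaluated	PMCA3a	V14E/D	foldx	4.99
evaluated	PMCA3a	F18S	foldx	0.19
evaluated	PMCA4a_4c	L5R	foldx	-2.79
evaluated	PMCA4a_4c	N6I	foldx	1.72
evaluated	PMCA4a_4c	I8T	foldx	3.77
evaluated	PMCA4a_4c	V14E/D	foldx	12.05
evaluated	PMCA4a_4c	F18S	foldx	7.9
evaluated	PMCA4b	L5R	foldx	2.6
evaluated	PMCA4b	N6I	foldx	8.06
evaluated	PMCA4b	I8T	foldx	5.43
evaluated	PMCA4b	V14E/D	foldx	16.12
evaluated	PMCA4b	F18S	foldx	3.73
evaluated	PMCA1a	L5R	mutabind2	1.98
evaluated	PMCA1a	N6I	mutabind2	0.32
evaluated	PMCA1a	I8T	mutabind2	0.32
evaluated	PMCA1a	V14E/D	mutabind2	2.95
evaluated	PMCA1a	F18S	mutabind2	5.04
evaluated	PMCA1b	L5R	mutabind2	0.21
evaluated	PMCA1b	N6I	mutabind2	0.31
evaluated	PMCA1b	I8T	mutabind2	2.5
evaluated	PMCA1b	V14E/D	mutabind2	3.13
evaluated	PMCA1b	F18S	mutabind2	4.23
evaluated	PMCA2a_2b_3b	L5R	mutabind2	1.9
evaluated	PMCA2a_2b_3b	N6I	mutabind2	0.85
evaluated	PMCA2a_2b_3b	I8T	mutabind2	2.53
evaluated	PMCA2a_2b_3b	V14E/D	mutabind2	3.67
evaluated	PMCA2a_2b_3b	F18S	mutabind2	4.2
evaluated	PMCA2c_2d	L5R	mutabind2	1.72
evaluated	PMCA2c_2d	N6I	mutabind2	0.72
evaluated	PMCA2c_2d	I8T	mutabind2	2.57
evaluated	PMCA2c_2d	V14E/D	mutabind2	3.77
evaluated	PMCA2c_2d	F18S	mutabind2	4.33
evaluated	PMCA3a	L5R	mutabind2	2.6
evaluated	PMCA3a	N6I	mutabind2	1.56
evaluated	PMCA3a	I8T	mutabind2	2.9
evaluated	PMCA3a	V14E/D	mutabind2	3.35
evaluated	PMCA3a	F18S	mutabind2	4.57
evaluated	PMCA4a_4c	L5R	mutabind2	1.85
evaluated	PMCA4a_4c	N6I	mutabind2	0.05
evaluated	PMCA4a_4c	I8T	mutabind2	2.97
evaluated	PMCA4a_4c	V14E/D	mutabind2	3.45
evaluated	PMCA4a_4c	F18S	mutabind2	4.59
evaluated	PMCA4b	L5R	mutabind2	1.92
evaluated	PMCA4b	N6I	mutabind2	0.22
evaluated	PMCA4b	I8T	mutabind2	2.77
evaluated	PMCA4b	V14E/D	mutabind2	2.91
evaluated	PMCA4b	F18S	mutabind2	4.61
literature	PMCA2b	V1143F	foldx	1.98
literature	PMCA3b	W1104A	foldx	15.88
literature	PMCA3b	G1107D	foldx	9.29
literature	PMCA2b	V1143F	mutabind2	4.24
literature	PMCA3b	W1104A	mutabind2	3.51
literature	PMCA3b	G1107D	mutabind2	2.39
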