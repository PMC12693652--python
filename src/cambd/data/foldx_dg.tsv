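Pdb	Group1	Group2	Interaction Energy
PMCA1a_WT_CaM.pdb	A	B	-48.22
PMCA2a_2b_3b_WT_CaM.pdb	A	B	-61.92
PMCA4b_WT_CaM.pdb	A	B	-59.20
PMCA2b_V1143F_CaM.pdb	A	B	-59.94
PMCA3b_W1104A_CaM.pdb	A	B	-46.04
PMCA3b_G1107D_CaM.pdb	A	B	-50.65
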