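# Explicit mutant-complex -> wild-type-complex pairing for binding-energy
# differences.  Pairing is never inferred from labels; the printed 9.29 for
# PMCA3b G1107D is inconsistent with any printed wild-type energy and is
# logged by the energetics driver when recomputed.
PMCA2b_V1143F_CaM.pdb: PMCA2a_2b_3b_WT_CaM.pdb
PMCA3b_W1104A_CaM.pdb: PMCA2a_2b_3b_WT_CaM.pdb
PMCA3b_G1107D_CaM.pdb: PMCA2a_2b_3b_WT_CaM.pdb
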