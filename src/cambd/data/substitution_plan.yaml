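# Single-nucleotide substitution plan for the 18-residue CaM-binding window.
# Keys are motif positions (1-18); values list the target codons reachable by
# editing the configured codon position.  Shipped defaults realize
# L5R, N6I, I8T, V14E/D and F18S across the PMCA window groups.
codon_position: 2
entries:
  5: [cgg]
  6: [atc, att]
  8: [acc, act]
  14: [gaa, gag, gac]
  18: [tct, tcc]
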