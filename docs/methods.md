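# Methods

## Window delimitation

Isoform sequences are scanned ungapped for the C28 reference peptide of
PMCA4b with a sliding-window identity score (matches / 28). The leftmost
window attaining the maximal identity wins; a hit requires identity ≥
`min_identity` (default 0.6 — permissive enough for cross-isoform and
ortholog scans, strict enough to reject random matches, whose expected
identity on a 20-letter alphabet is ~0.05). The 18-residue CaMBD window
starts at the W aligned to C28 position 8, so window positions 1–18 map
to PMCA4b residues 1093–1110; the mapping is stored as a numbering
offset (1092). W1/F18 anchor enforcement is a flag: by default a
deviating window warns rather than fails, because ortholog windows can
vary at the anchors.

Windows identical at the residue level across splice variants are
collapsed into one group. Group labels keep the shared alphabetic
prefix once (`PMCA2a_2b_3b`), members in input order. Members of a
group may still differ silently at the codon level (PMCA2c `gtc` vs
PMCA2d `gta` at window position 14); the group carries the first
member's codons, which is also what the published per-group codon grid
tabulates. Nucleotides are normalized to lower case and amino acids to
upper case on ingest; CDS records must translate exactly to their
protein (a single terminal stop is tolerated, an internal stop is an
error).

## Conservation and covariation

*Stars.* For each window position, the star count is the number of the
three intra-codon nucleotide positions at which every isoform carries
the same base (0–3); 3 means the codon is fully invariant.

*Weights.* "Phylogeny-aware" row weighting is realized as Henikoff
position-based weighting: in each column every residue type shares its
weight equally among the rows carrying it, a row's weight is its mean
share over columns, and weights are normalized to sum to 1. The exact
scheme of the original web tool is not published; Henikoff weighting is
the standard tree-free surrogate, and externally computed weights can
be supplied instead (every function accepts a weight vector).

*Weighted MI.* For columns i, j the joint distribution over observed
symbols is accumulated from row weights; rows gapped in either column
are dropped from that pair and the remaining weights renormalized. An
optional pseudocount (default 0, for exactness on small alignments) is
added per observed-alphabet cell before normalization. The score is
MI/min(H(i), H(j)) in bits, defined as 0 when either column is
invariant, clipped to [0, 1]. With equal weights and pseudocount 0 this
reduces to plain joint-count MI, which is how the tests oracle it.

*Clustering.* Columns are agglomerated by average linkage on distance
1 − score. The agglomeration is written out (≈30 lines) rather than
delegated so that ties break deterministically toward the lowest
cluster ids; heights are cross-checked against scipy's average linkage
on tie-free random matrices in the tests. Merge lists export to Newick
with heights as node depths.

## Variant enumeration

Each codon has exactly 9 single-base neighbours, 3 per codon position.
Edits are classified by standard-code translation as synonymous,
missense or nonsense; stops never form a substitution class. The screen
targets the second codon position, where degeneracy is lowest and a
single change almost always alters the residue; positions 1 and 3 are
supported for generality. Because no rule is published for choosing
among the three alternatives at a position (e.g. N6→I rather than
N6→T/S), the choice is configuration: a YAML plan maps motif positions
to target codons, and the shipped plan realizes L5R, N6I, I8T, V14E/D
and F18S. Realization applies, per group and position, the target codon
differing from the group codon at exactly the configured position; a
target that is a single-base neighbour at the *wrong* position is an
error, and positions with no applicable target are reported unmatched.

## Model confidence and structural QC

Replicate ipTM scores (five models per complex) are summarized as
mean ± t·sd/√n with the two-sided Student-t multiplier at the requested
level (default 0.95) and the sample (n−1) standard deviation. Display
bounds are rounded to 2 decimals with trailing zeros trimmed
("[0.64-0.7]"); raw values are kept in machine output. Recomputed
bounds are compared row-wise against the packaged printed bounds; all
45 rows of the packaged grid agree. Discrepancies, had there been any,
would be reported, never corrected. Best-model selection is the ipTM
argmax with ties to the lowest model index.

RMSD uses the Kabsch construction: centroid removal, optimal rotation
by SVD with the determinant sign corrected so reflections are
disallowed, atoms matched by (chain, residue number, atom name),
default selection Cα. φ/ψ torsions follow the IUPAC sign convention
(validated against an independent geometry oracle); termini yield
undefined angles and are excluded from the favored-fraction
denominator. The favored-region map is a deliberately coarse set of
rectangles — αR: φ∈[−160,−20], ψ∈[−120,50]; β: φ∈[−180,−45],
ψ∈[90,180]∪[−180,−150]; αL: φ∈[20,100], ψ∈[−20,90] — adequate for
sanity checks on idealized fixtures, not calibrated against a
reference-density favored/allowed atlas; any callable (φ,ψ)→bool can
replace it.

## Energetics

ΔΔG = ΔG_substituted − ΔG_wild-type, wild-type pairing always explicit
via a mapping file (never inferred from labels — one tabulated
literature value, 9.29 kcal/mol for the PMCA3b G→D complex, is
inconsistent with every tabulated wild-type energy, and the driver logs
this instead of guessing a pairing; the arithmetic from the energies
gives 11.27). Classification uses strict inequalities: an effect
requires |ΔΔG| to exceed the band (1.7 kcal/mol FoldX-style — twice the
method's 0.85 kcal/mol error — or 1.5 kcal/mol MutaBind2-style), so a
value of exactly 1.7 is within error and 1.72 is weakening. This
matters: the evaluated grid contains 1.72, and the boundary convention
is what makes the cohort come out at 14 within-cutoff records of 70.
Energies are carried at their printed 2-decimal precision; no unit
conversion is ever applied.

## Disease context

Gene–disease association records are filtered by confidence score
(≥0.3 general, ≥0.5 high-confidence) and by variant-level association
types (CausalMutation, GeneticVariation). Polygenicity is the number of
genes linked to the disease: 1 monogenic, 2 oligogenic, ≥3 polygenic,
with a low/high stratum split at ≤30 vs >30 genes — an operational
prioritization boundary, not a biological constant. Damage-score
categories use half-open bins (<0.2 benign, [0.2, 0.85) possibly
damaging, ≥0.85 probably damaging), so the 0.85 boundary is probably
damaging. Records pass through unmerged: no cross-gene disease
deduplication rule is imposed. All inputs are static CSV exports;
organ-system mapping, if used, is a user-supplied two-column join.

## Synthetic fixtures

Generators draw from `numpy.random.default_rng([seed, stream])` with a
fixed stream id per generator family, so fixtures are reproducible at
the byte level and adding one generator never shifts another. Defaults
mirror the study conditions: 11 isoforms over 4 genes sharing the
PMCA4b window with 15% per-site interior divergence (anchors exempt) —
matching the observed pattern that variability concentrates in the
window's C-terminal half — CDS by uniform choice among synonymous
codons; 5 ipTM replicates per complex from a Gaussian at μ=0.65,
σ=0.03 (the wild-type grid's scale), clamped to [0,1]; a 70-record
energy cohort with planted weakening/strengthening/within-error
proportions apportioned exactly (largest remainder) and magnitudes
drawn strictly outside or inside the cutoff band, so planted labels are
recovered with certainty; association tables cycling linked-gene counts
through all polygenicity classes and both strata.

What the fixtures do *not* emulate: predictor geometry or physics (no
structural realism behind the ipTM numbers, no force-field behind the
ΔΔG draws), alignment gaps in the isoform family, and base-composition
or transition/transversion structure in the CDS. Tests passing on these
fixtures therefore validate the pipeline's arithmetic, contracts and
determinism — not the external predictors' accuracy on real data.

## Problem sizes

The packaged reference grids are small (11×18 codons, 45×5 replicate
rows, 76 energy records), so every golden check runs in well under a
second. The coverage simulation uses 2,000 five-replicate sets, enough
to pin the empirical 95% coverage inside [0.93, 0.97] with comfortable
margin; the MI oracle comparisons use ≤6×6 alignments where brute-force
joint counting is exact and instant.

## Known limitations

- The normalized weighted-MI scores reproduce the *structure* of the
  published covariation analysis (bounded scores, cluster cohesion in
  the window's C-terminal half), not the web server's exact numbers,
  whose weighting is undisclosed.
- Printed-value grids are transcriptions; the package treats them as
  inputs and recomputes everything derivable from them, logging (not
  silently fixing) internal inconsistencies.
- RMSD against the experimental 2KNE complex requires the authors'
  undeposited predicted models and is therefore covered by invariance
  and oracle properties of the Kabsch implementation instead of a
  numeric golden value.
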