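"""Score per-position conservation and column covariation over the
18-column window alignment.

Computes the nucleotide-conservation star vector from the isoform codon
grid, Henikoff sequence weights and the normalized weighted-MI matrix over
the residue alignment, and an average-linkage dendrogram of columns.
Writes results/conservation.tsv, results/covariation.tsv and
results/covariation_tree.nwk.
"""

from pathlib import Path

import pandas as pd

from cambd.conservation import (
    MsaBlock,
    cluster_covariation,
    column_identity,
    merges_to_newick,
    sequence_weights,
    star_vector,
    weighted_mutual_information,
)
from cambd.reference import load_codon_grid, load_isoform_windows

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = load_codon_grid()
    codon_cols = [list(grid[f"T{i:02d}"]) for i in range(1, 19)]
    stars = star_vector(codon_cols)

    windows = load_isoform_windows()
    msa = MsaBlock([(w.member_isoforms[0], w.residues) for w in windows])
    weights = sequence_weights(msa)
    identities = [column_identity(msa.column(j), weights) for j in range(msa.n_cols)]

    labels = [f"{msa.rows[0][1][j]}{j + 1}" for j in range(msa.n_cols)]
    cons = pd.DataFrame(
        {"position": range(1, 19), "column": labels, "stars": stars, "identity": identities}
    )
    cons.to_csv(OUT / "conservation.tsv", sep="\t", index=False, float_format="%.4f")

    matrix = weighted_mutual_information(msa, weights)
    cov = pd.DataFrame(matrix.scores, index=labels, columns=labels)
    cov.to_csv(OUT / "covariation.tsv", sep="\t", float_format="%.4f")
    merges = cluster_covariation(matrix)
    (OUT / "covariation_tree.nwk").write_text(merges_to_newick(merges, labels) + "\n")

    print("star vector:", " ".join(str(s) for s in stars))
    fully = [labels[i] for i, s in enumerate(stars) if s == 3]
    print("fully conserved codons:", ", ".join(fully))
    pairs = [
        (labels[i], labels[j], matrix.scores[i, j])
        for i in range(18)
        for j in range(i + 1, 18)
    ]
    top = sorted(pairs, key=lambda t: -t[2])[:5]
    print("top covarying column pairs (normalized weighted MI):")
    for a, b, s in top:
        print(f"  {a:<4} {b:<4} {s:.3f}")
    print(f"wrote {OUT / 'conservation.tsv'}, covariation.tsv, covariation_tree.nwk")


if __name__ == "__main__":
    main()
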