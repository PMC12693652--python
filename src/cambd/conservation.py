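"""Conservation and co-evolution scoring over the 18-column CaMBD alignment.

Per-position signals come in two flavours: codon-level conservation stars
(how many of the three intra-codon nucleotide positions are invariant
across isoforms) and residue-level weighted identity.  Covariation between
alignment columns is measured with mutual information computed from
sequence-weighted residue frequencies and normalized by the smaller column
entropy, giving scores in [0, 1].  Columns are then grouped by average-
linkage agglomeration on 1 - score, exportable as a Newick dendrogram.

Sequence weighting uses the Henikoff & Henikoff position-based scheme:
within each column every residue type shares its weight equally among the
rows carrying it, and a row's weight is its mean share over columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

GAP = "-"

__all__ = [
    "MsaBlock",
    "CovariationMatrix",
    "conservation_stars",
    "star_vector",
    "column_identity",
    "sequence_weights",
    "weighted_mutual_information",
    "cluster_covariation",
    "merges_to_newick",
]


@dataclass
class MsaBlock:
    """A gapped alignment block: rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        n = len(self.rows[0][1])
        self.rows = [(label, seq.upper()) for label, seq in self.rows]
        if any(len(seq) != n for _, seq in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.rows]

    @classmethod
    def from_fasta(cls, path) -> "MsaBlock":
        return cls([(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")])


@dataclass
class CovariationMatrix:
    """Symmetric normalized covariation scores over alignment columns."""

    scores: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("scores must be square")
        if len(self.column_labels) != self.scores.shape[0]:
            raise ValueError("one label per column required")


def conservation_stars(codons: list[str]) -> int:
    """Count intra-codon nucleotide positions identical across all codons.

    Returns 0-3; 3 means the codon is fully conserved in the column.
    """
    if not codons:
        raise ValueError("empty codon column")
    codons = [c.lower() for c in codons]
    if any(len(c) != 3 for c in codons):
        raise ValueError("codons must be triplets")
    return sum(1 for k in range(3) if len({c[k] for c in codons}) == 1)


def star_vector(codon_columns: list[list[str]]) -> list[int]:
    """Star counts for each of a list of codon columns."""
    return [conservation_stars(col) for col in codon_columns]


def column_identity(column: list[str], weights: np.ndarray | None = None) -> float:
    """Weighted frequency of the modal residue in an alignment column.

    Gap rows are dropped and the remaining weights renormalized; an
    all-gap column is an error.
    """
    column = [c.upper() for c in column]
    if weights is None:
        weights = np.full(len(column), 1.0 / len(column))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(column):
        raise ValueError("one weight per row required")
    keep = [i for i, c in enumerate(column) if c != GAP]
    if not keep:
        raise ValueError("all-gap column")
    w = weights[keep]
    w = w / w.sum()
    freq: dict[str, float] = {}
    for wi, i in zip(w, keep):
        freq[column[i]] = freq.get(column[i], 0.0) + wi
    return max(freq.values())


def sequence_weights(msa: MsaBlock) -> np.ndarray:
    """Henikoff position-based row weights, normalized to sum to 1.

    Redundant rows share weight, so divergent rows count more — a cheap
    stand-in for phylogenetic weighting that needs no tree.  Gap cells
    contribute nothing in their column.
    """
    n, m = msa.n_rows, msa.n_cols
    contrib = np.zeros((n, m))
    for j in range(m):
        col = msa.column(j)
        types = [c for c in col if c != GAP]
        if not types:
            continue
        counts: dict[str, int] = {}
        for c in types:
            counts[c] = counts.get(c, 0) + 1
        k = len(counts)
        for i, c in enumerate(col):
            if c != GAP:
                contrib[i, j] = 1.0 / (k * counts[c])
    w = contrib.mean(axis=1)
    total = w.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return w / total


def _pair_distribution(
    col_i: list[str], col_j: list[str], weights: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Weighted joint distribution over the observed symbol alphabet.

    Rows gapped in either column are dropped (weights renormalized);
    returns None when nothing remains.  The pseudocount is added to every
    cell of the observed-alphabet grid before normalization.
    """
    keep = [k for k in range(len(col_i)) if col_i[k] != GAP and col_j[k] != GAP]
    if not keep:
        return None
    w = weights[keep]
    w = w / w.sum()
    sym_i = sorted({col_i[k] for k in keep})
    sym_j = sorted({col_j[k] for k in keep})
    idx_i = {s: a for a, s in enumerate(sym_i)}
    idx_j = {s: b for b, s in enumerate(sym_j)}
    joint = np.full((len(sym_i), len(sym_j)), float(pseudocount))
    for wk, k in zip(w, keep):
        joint[idx_i[col_i[k]], idx_j[col_j[k]]] += wk
    joint /= joint.sum()
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def weighted_mutual_information(
    msa: MsaBlock, weights: np.ndarray | None = None, pseudocount: float = 0.0
) -> CovariationMatrix:
    """Covariation matrix of normalized weighted mutual information.

    For columns i, j:  MI = sum_ab p(a,b) log2(p(a,b) / (p(a) p(b))) with
    sequence-weighted frequencies, normalized by min(H(i), H(j)); pairs
    where either column is invariant score 0.  Scores lie in [0, 1] and
    the matrix is symmetric with a zero diagonal.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if weights is None:
        weights = sequence_weights(msa)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != msa.n_rows:
        raise ValueError("one weight per alignment row required")
    m = msa.n_cols
    cols = [msa.column(j) for j in range(m)]
    scores = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist = _pair_distribution(cols[i], cols[j], weights, pseudocount)
            if dist is None:
                continue
            joint, pi, pj = dist
            h_min = min(_entropy(pi), _entropy(pj))
            if h_min <= 0:
                continue
            mi = 0.0
            for a in range(joint.shape[0]):
                for b in range(joint.shape[1]):
                    if joint[a, b] > 0 and pi[a] > 0 and pj[b] > 0:
                        mi += joint[a, b] * np.log2(joint[a, b] / (pi[a] * pj[b]))
            scores[i, j] = scores[j, i] = min(max(mi / h_min, 0.0), 1.0)
    labels = [f"C{j + 1}" for j in range(m)]
    return CovariationMatrix(scores=scores, column_labels=labels)


def cluster_covariation(matrix: CovariationMatrix) -> list[tuple[int, int, float]]:
    """Average-linkage agglomeration on distance 1 - score.

    Returns merges as (child_a, child_b, height) with leaves numbered
    0..n-1 and merged clusters n, n+1, ... in merge order (the scipy
    linkage id convention).  Ties break toward the lowest cluster ids.
    """
    d0 = 1.0 - matrix.scores
    n = d0.shape[0]
    if not np.allclose(d0, d0.T):
        raise ValueError("covariation matrix must be symmetric")
    if n < 2:
        return []
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(members)
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                d = float(np.mean([d0[x, y] for x in members[a] for y in members[b]]))
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append((a, b, d))
        members[next_id] = members.pop(a) + members.pop(b)
        active = sorted(members)
        next_id += 1
    return merges


def merges_to_newick(merges: list[tuple[int, int, float]], labels: list[str]) -> str:
    """Render a merge list as a Newick string with heights as node depths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for k, (a, b, h) in enumerate(merges):
        nid = n + k
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[nid] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[nid] = h
    root = n + len(merges) - 1 if merges else 0
    return node[root] + ";"
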