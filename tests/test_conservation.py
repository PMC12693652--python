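"""Conservation stars, weighted identity, weighted MI, and clustering."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from cambd.conservation import (
    CovariationMatrix,
    MsaBlock,
    cluster_covariation,
    column_identity,
    conservation_stars,
    merges_to_newick,
    sequence_weights,
    star_vector,
    weighted_mutual_information,
)
from tests.conftest import PRINTED_STARS


class TestConservationStars:
    def test_grid_star_vector_matches_printed_row(self, codon_grid):
        cols = [list(codon_grid[f"T{i:02d}"]) for i in range(1, 19)]
        assert tuple(star_vector(cols)) == PRINTED_STARS

    @pytest.mark.parametrize(
        "codons,stars",
        [
            (["tgg", "tgg", "tgg"], 3),
            (["aga", "cgg", "cga", "cgt"], 1),
            (["gat", "cga", "gac", "gaa", "gag", "aaa", "cgc", "cgg"], 0),
        ],
    )
    def test_examples(self, codons, stars):
        assert conservation_stars(codons) == stars

    def test_three_stars_iff_identical(self):
        rng = np.random.default_rng(5)
        bases = "acgt"
        for _ in range(50):
            codons = ["".join(bases[i] for i in rng.integers(0, 4, 3)) for _ in range(4)]
            s = conservation_stars(codons)
            assert 0 <= s <= 3
            assert (s == 3) == (len(set(codons)) == 1)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            conservation_stars([])


class TestColumnIdentity:
    def test_fully_conserved(self):
        assert column_identity(["L"] * 5) == 1.0

    def test_two_state_symmetry(self):
        assert column_identity(["W", "F"]) == 0.5

    def test_weighted_mode(self):
        assert column_identity(["N", "N", "S"], np.array([0.25, 0.25, 0.5])) == pytest.approx(0.5)

    def test_gaps_dropped_and_renormalized(self):
        assert column_identity(["A", "-", "A", "B"]) == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            column_identity(["-", "-"])


class TestSequenceWeights:
    def test_identical_rows_get_equal_weights(self):
        msa = MsaBlock([("a", "WFRG"), ("b", "WFRG"), ("c", "WFRG")])
        assert np.allclose(sequence_weights(msa), 1 / 3)

    def test_divergent_row_upweighted(self):
        # Henikoff hand computation: AT gets (1/3 + 1/2)/2, AA (1/3 + 1/4)/2
        msa = MsaBlock([("r1", "AA"), ("r2", "AA"), ("r3", "AT")])
        w = sequence_weights(msa)
        assert w[2] > w[0] == w[1]
        assert np.allclose(w, [7 / 24, 7 / 24, 5 / 12])

    def test_single_row(self):
        assert sequence_weights(MsaBlock([("r", "WF")]))[0] == 1.0

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(11)
        rows = [("r%d" % i, "".join("ACDG"[j] for j in rng.integers(0, 4, 6))) for i in range(5)]
        assert sequence_weights(MsaBlock(rows)).sum() == pytest.approx(1.0)


def _mi_oracle(col_i, col_j):
    """Brute-force unweighted normalized MI from joint counts."""
    pairs = [(a, b) for a, b in zip(col_i, col_j) if a != "-" and b != "-"]
    n = len(pairs)
    joint = {}
    for p in pairs:
        joint[p] = joint.get(p, 0) + 1
    pa, pb = {}, {}
    for (a, b), c in joint.items():
        pa[a] = pa.get(a, 0) + c
        pb[b] = pb.get(b, 0) + c
    mi = sum(
        (c / n) * np.log2((c / n) / ((pa[a] / n) * (pb[b] / n))) for (a, b), c in joint.items()
    )
    ha = -sum((c / n) * np.log2(c / n) for c in pa.values())
    hb = -sum((c / n) * np.log2(c / n) for c in pb.values())
    hmin = min(ha, hb)
    return 0.0 if hmin <= 0 else mi / hmin


class TestWeightedMutualInformation:
    def test_invariant_column_scores_zero(self):
        msa = MsaBlock([("a", "LW"), ("b", "LF"), ("c", "LY")])
        m = weighted_mutual_information(msa, np.full(3, 1 / 3))
        assert m.scores[0, 1] == 0.0

    def test_perfect_covariation_scores_one(self):
        msa = MsaBlock([("1", "AC"), ("2", "AC"), ("3", "BD"), ("4", "BD")])
        m = weighted_mutual_information(msa, np.full(4, 0.25), pseudocount=0.0)
        assert m.scores[0, 1] == pytest.approx(1.0)

    def test_independent_columns_score_zero(self):
        msa = MsaBlock([("1", "AC"), ("2", "AD"), ("3", "BC"), ("4", "BD")])
        m = weighted_mutual_information(msa, np.full(4, 0.25), pseudocount=0.0)
        assert m.scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_small_alignments(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_rows = int(rng.integers(2, 7))
            n_cols = int(rng.integers(2, 7))
            rows = [
                ("r%d" % i, "".join("ABCD-"[j] for j in rng.integers(0, 5, n_cols)))
                for i in range(n_rows)
            ]
            try:
                msa = MsaBlock(rows)
                m = weighted_mutual_information(msa, np.full(n_rows, 1 / n_rows), pseudocount=0.0)
            except ValueError:
                continue  # all-gap pathological draw
            for i, j in itertools.combinations(range(n_cols), 2):
                col_i, col_j = msa.column(i), msa.column(j)
                if all(a == "-" or b == "-" for a, b in zip(col_i, col_j)):
                    continue
                assert m.scores[i, j] == pytest.approx(_mi_oracle(col_i, col_j), abs=1e-9)

    def test_symmetry_bounds_and_row_permutation_invariance(self):
        rng = np.random.default_rng(31)
        rows = [("r%d" % i, "".join("ACDEF"[j] for j in rng.integers(0, 5, 8))) for i in range(6)]
        msa = MsaBlock(rows)
        w = sequence_weights(msa)
        m = weighted_mutual_information(msa, w)
        assert np.allclose(m.scores, m.scores.T)
        assert (m.scores >= 0).all() and (m.scores <= 1).all()
        perm = rng.permutation(6)
        msa_p = MsaBlock([rows[i] for i in perm])
        m_p = weighted_mutual_information(msa_p, w[perm])
        assert np.allclose(m.scores, m_p.scores)


class TestClusterCovariation:
    def test_two_columns_single_merge(self):
        m = CovariationMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ["C1", "C2"])
        assert cluster_covariation(m) == [(0, 1, pytest.approx(0.6))]

    def test_blocks_merge_internally_first(self):
        s = np.zeros((4, 4))
        s[0, 1] = s[1, 0] = 1.0
        s[2, 3] = s[3, 2] = 1.0
        merges = cluster_covariation(CovariationMatrix(s, list("ABCD")))
        assert merges[0] == (0, 1, 0.0) and merges[1] == (2, 3, 0.0)
        assert merges[2][2] == pytest.approx(1.0)

    def test_merge_heights_non_decreasing_and_match_scipy(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            s = rng.uniform(0, 1, (n, n))
            s = (s + s.T) / 2
            np.fill_diagonal(s, 0.0)
            merges = cluster_covariation(CovariationMatrix(s, [f"C{i}" for i in range(n)]))
            heights = [h for _, _, h in merges]
            assert heights == sorted(heights)
            z = linkage(squareform(1.0 - s, checks=False), method="average")
            assert np.allclose(sorted(heights), sorted(z[:, 2]))

    def test_newick_export_parses(self):
        from io import StringIO

        from Bio import Phylo

        s = np.array([[0, 0.9, 0.1], [0.9, 0, 0.2], [0.1, 0.2, 0]], dtype=float)
        merges = cluster_covariation(CovariationMatrix(s, ["W1", "V14", "F18"]))
        tree = Phylo.read(StringIO(merges_to_newick(merges, ["W1", "V14", "F18"])), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["F18", "V14", "W1"]
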