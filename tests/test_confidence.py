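"""Student-t summaries, model ranking, Kabsch RMSD and dihedral QC."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cambd.confidence import (
    Atom,
    CoordinateSet,
    backbone_dihedrals,
    check_printed_bounds,
    favored_fraction,
    format_bound,
    kabsch_rmsd,
    select_best,
    summarize_iptm,
    superpose_rmsd,
)


class TestSummarizeIptm:
    def test_reference_wt_rows_reproduce_printed_bounds(self):
        s1a = summarize_iptm([0.71, 0.68, 0.67, 0.65, 0.65])
        assert (format_bound(s1a.ci_lo), format_bound(s1a.ci_hi)) == ("0.64", "0.7")
        s4b = summarize_iptm([0.74, 0.65, 0.65, 0.62, 0.59])
        assert (format_bound(s4b.ci_lo), format_bound(s4b.ci_hi)) == ("0.58", "0.72")

    def test_full_replicate_grid_consistent_with_printed_intervals(self, iptm_table):
        checked = check_printed_bounds(iptm_table)
        assert checked["match"].all()

    def test_constant_replicates_give_zero_width(self):
        s = summarize_iptm([0.5] * 5)
        assert s.ci_lo == s.ci_hi == s.mean == 0.5

    def test_interval_contains_mean_and_widens_with_level_and_sd(self):
        values = [0.6, 0.62, 0.64, 0.7, 0.71]
        s90 = summarize_iptm(values, level=0.90)
        s99 = summarize_iptm(values, level=0.99)
        assert s90.ci_lo <= s90.mean <= s90.ci_hi
        assert (s99.ci_hi - s99.ci_lo) > (s90.ci_hi - s90.ci_lo)
        wide = summarize_iptm([0.4, 0.5, 0.64, 0.8, 0.9])
        assert (wide.ci_hi - wide.ci_lo) > (s90.ci_hi - s90.ci_lo)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize_iptm([0.7])


class TestSelectBest:
    @pytest.mark.parametrize(
        "values,best",
        [
            ([0.71, 0.68, 0.67, 0.65, 0.65], 0),
            ([0.5, 0.5, 0.5], 0),
            ([0.2, 0.9], 1),
        ],
    )
    def test_argmax_with_lowest_index_ties(self, values, best):
        assert select_best(values) == best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestKabschRmsd:
    def _cloud(self, seed, n=12):
        return np.random.default_rng(seed).normal(size=(n, 3))

    def test_identical_sets_zero(self):
        a = self._cloud(1)
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance_and_symmetry(self):
        a = self._cloud(2)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            b = (rot @ a.T).T + np.array([1.0, -2.0, 3.0])
            assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)
        c = self._cloud(3)
        assert kabsch_rmsd(a, c) == pytest.approx(kabsch_rmsd(c, a), abs=1e-9)

    def test_agrees_with_scipy_align_vectors_oracle(self):
        a = self._cloud(4)
        b = self._cloud(5)
        ac, bc = a - a.mean(0), b - b.mean(0)
        _, rssd = Rotation.align_vectors(bc, ac)
        assert kabsch_rmsd(a, b) == pytest.approx(rssd / math.sqrt(len(a)), abs=1e-8)

    def test_single_displaced_point_toy(self):
        a = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float)
        b = a.copy()
        b[0, 2] = 1.0  # 1 A out of plane
        _, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert kabsch_rmsd(a, b) == pytest.approx(rssd / 2.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Place the next atom from bond length, angle and torsion (NeRF)."""
    theta, chi = math.radians(theta_deg), math.radians(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(chi), r * math.sin(theta) * math.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_chain(phi, psi, n_res=6):
    """Ideal backbone with uniform (phi, psi), omega = 180."""
    coords = {}
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([math.cos(math.radians(180 - 111.2)), math.sin(math.radians(180 - 111.2)), 0.0])
    coords[(1, "N")], coords[(1, "CA")], coords[(1, "C")] = n, ca, c
    for i in range(2, n_res + 1):
        n = _nerf(coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")], 1.329, 116.2, psi)
        ca = _nerf(coords[(i - 1, "CA")], coords[(i - 1, "C")], n, 1.458, 121.7, 180.0)
        c = _nerf(coords[(i - 1, "C")], n, ca, 1.525, 111.2, phi)
        coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")] = n, ca, c
    atoms = [
        Atom("A", i, "ALA", name, *coords[(i, name)])
        for i in range(1, n_res + 1)
        for name in ("N", "CA", "C")
    ]
    return CoordinateSet(atoms)


class TestBackboneDihedrals:
    def test_ideal_helix_recovers_set_torsions(self):
        cs = _build_chain(phi=-57.0, psi=-47.0)
        dihedrals = backbone_dihedrals(cs)
        for _, num, phi, psi in dihedrals:
            if phi is not None:
                assert phi == pytest.approx(-57.0, abs=1e-6)
            if psi is not None:
                assert psi == pytest.approx(-47.0, abs=1e-6)

    def test_terminus_rule_on_two_residue_chain(self):
        cs = _build_chain(phi=-57.0, psi=-47.0, n_res=2)
        [(_, _, phi1, psi1), (_, _, phi2, psi2)] = backbone_dihedrals(cs)
        assert phi1 is None and psi1 is not None
        assert phi2 is not None and psi2 is None

    def test_torsions_agree_with_gemmi_oracle(self):
        import gemmi

        rng = np.random.default_rng(9)
        cs = _build_chain(phi=-120.0, psi=130.0, n_res=4)
        pos = {(a.res_num, a.atom_name): gemmi.Position(a.x, a.y, a.z) for a in cs.atoms}
        for _, num, phi, psi in backbone_dihedrals(cs):
            if phi is not None:
                ref = math.degrees(
                    gemmi.calculate_dihedral(
                        pos[(num - 1, "C")], pos[(num, "N")], pos[(num, "CA")], pos[(num, "C")]
                    )
                )
                assert phi == pytest.approx(ref, abs=1e-6)

    def test_missing_backbone_atoms_skipped_with_warning(self):
        cs = _build_chain(phi=-57.0, psi=-47.0, n_res=3)
        broken = CoordinateSet([a for a in cs.atoms if not (a.res_num == 2 and a.atom_name == "CA")])
        with pytest.warns(UserWarning):
            dihedrals = backbone_dihedrals(broken)
        assert [num for _, num, _, _ in dihedrals] == [1, 3]


class TestFavoredFraction:
    def test_helical_chain_fully_favored(self):
        cs = _build_chain(phi=-57.0, psi=-47.0)
        assert favored_fraction(backbone_dihedrals(cs)) == pytest.approx(100.0)

    def test_mixed_fixture_counts_directly(self):
        dihedrals = [
            ("A", 1, -57.0, -47.0),   # alpha-R
            ("A", 2, -120.0, 130.0),  # beta
            ("A", 3, 60.0, 40.0),     # alpha-L
            ("A", 4, 0.0, 180.0),     # outside all boxes
        ]
        assert favored_fraction(dihedrals) == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            favored_fraction([("A", 1, None, -47.0)])


class TestSuperposeRmsd:
    def test_matched_ca_selection(self):
        cs = _build_chain(phi=-57.0, psi=-47.0)
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = CoordinateSet(
            [
                Atom(a.chain, a.res_num, a.res_name, a.atom_name, *(rot @ np.array([a.x, a.y, a.z]) + 5.0))
                for a in cs.atoms
            ]
        )
        assert superpose_rmsd(cs, moved) == pytest.approx(0.0, abs=1e-6)

    def test_unmatched_selection_rejected(self):
        cs = _build_chain(phi=-57.0, psi=-47.0)
        shorter = CoordinateSet(cs.atoms[:-3])
        with pytest.raises(ValueError):
            superpose_rmsd(cs, shorter)
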