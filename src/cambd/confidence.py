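"""Model-confidence summaries and structural QC for predicted complexes.

Structure predictors emit several replicate models per complex together
with 0-1 interface confidence scores (ipTM).  Replicates are summarized
with a Student-t confidence interval on the mean; the best model is the
ipTM argmax.  Structural QC covers least-squares rigid superposition RMSD
(Kabsch), backbone phi/psi torsions, and the fraction of residues falling
in coarse favored Ramachandran regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelConfidence",
    "ConfidenceSummary",
    "CoordinateSet",
    "Atom",
    "summarize_iptm",
    "format_bound",
    "select_best",
    "kabsch_rmsd",
    "superpose_rmsd",
    "backbone_dihedrals",
    "favored_fraction",
    "DEFAULT_FAVORED_BOXES",
    "check_printed_bounds",
]


@dataclass(frozen=True)
class ModelConfidence:
    """Confidence metrics of one replicate model of a complex."""

    complex_id: str
    model_index: int
    iptm: float
    ptm: float | None = None
    plddt: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.iptm <= 1:
            raise ValueError("iptm must be in [0, 1]")
        if self.ptm is not None and not 0 <= self.ptm <= 1:
            raise ValueError("ptm must be in [0, 1]")
        if self.plddt is not None and any(not 0 <= x <= 100 for x in self.plddt):
            raise ValueError("plddt entries must be in [0, 100]")


@dataclass
class ConfidenceSummary:
    complex_id: str
    n: int
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float
    level: float = 0.95
    best_model: int | None = None

    @property
    def display_interval(self) -> str:
        return f"[{format_bound(self.ci_lo)}-{format_bound(self.ci_hi)}]"


def summarize_iptm(
    values: list[float], level: float = 0.95, complex_id: str = ""
) -> ConfidenceSummary:
    """Student-t confidence interval for the mean of replicate ipTM scores.

    CI = mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n), with the sample
    (n-1) standard deviation.  Requires n >= 2.
    """
    values = [float(v) for v in values]
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 replicates for a confidence interval")
    if any(not 0 <= v <= 1 for v in values):
        raise ValueError("ipTM values must be in [0, 1]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    half = stats.t.ppf((1 + level) / 2, n - 1) * sd / math.sqrt(n)
    return ConfidenceSummary(
        complex_id=complex_id,
        n=n,
        mean=mean,
        sd=sd,
        ci_lo=mean - half,
        ci_hi=mean + half,
        level=level,
        best_model=select_best(values),
    )


def format_bound(x: float) -> str:
    """Round to 2 decimals and trim trailing zeros (0.70 -> "0.7")."""
    s = f"{round(x, 2):.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def select_best(models: list) -> int:
    """Index of the highest-ipTM model; ties go to the lowest index."""
    if not models:
        raise ValueError("empty model list")
    scores = [m.iptm if isinstance(m, ModelConfidence) else float(m) for m in models]
    return int(np.argmax(scores))  # argmax returns the first maximum


def check_printed_bounds(table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Recompute CI bounds for a replicate grid and compare to printed ones.

    ``table`` needs columns m0..m4 plus printed_lo/printed_hi; adds the
    recomputed bounds, their display strings and a ``match`` flag (equality
    of the trimmed 2-decimal representations).  Mismatches are reported,
    never corrected.
    """
    out = table.copy()
    model_cols = [c for c in table.columns if c.startswith("m") and c[1:].isdigit()]
    lo, hi, match = [], [], []
    for _, row in table.iterrows():
        s = summarize_iptm([row[c] for c in model_cols], level=level)
        lo.append(s.ci_lo)
        hi.append(s.ci_hi)
        match.append(
            format_bound(s.ci_lo) == format_bound(row["printed_lo"])
            and format_bound(s.ci_hi) == format_bound(row["printed_hi"])
        )
    out["ci_lo"], out["ci_hi"], out["match"] = lo, hi, match
    return out


# --- coordinates and structural QC -------------------------------------------


@dataclass(frozen=True)
class Atom:
    chain: str
    res_num: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float


@dataclass
class CoordinateSet:
    """A flat atom list keyed by (chain, residue number, atom name)."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        keys = [(a.chain, a.res_num, a.atom_name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom) keys")
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError("non-finite coordinates")

    @classmethod
    def from_file(cls, path: str | Path) -> "CoordinateSet":
        """Read PDB or mmCIF coordinates (first model only)."""
        st = gemmi.read_structure(str(path))
        atoms = []
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(
                        Atom(
                            chain=chain.name,
                            res_num=res.seqid.num,
                            res_name=res.name,
                            atom_name=atom.name,
                            x=atom.pos.x,
                            y=atom.pos.y,
                            z=atom.pos.z,
                        )
                    )
        return cls(atoms)

    def select(self, atom_names: set[str] | None = None) -> "CoordinateSet":
        if atom_names is None:
            return self
        return CoordinateSet([a for a in self.atoms if a.atom_name in atom_names])

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after least-squares rigid superposition of two Nx3 point sets.

    Centroids are removed and the optimal proper rotation found by SVD
    (determinant sign corrected so reflections are disallowed).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("inputs must be matched Nx3 arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ ac.T).T - bc
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def superpose_rmsd(
    a: CoordinateSet, b: CoordinateSet, atom_names: set[str] | None = frozenset({"CA"})
) -> float:
    """Kabsch RMSD over atoms matched by (chain, residue number, atom name).

    Default selection is the C-alpha trace.  Unmatched selections are an
    error rather than silently intersected away to nothing.
    """
    sel_a = a.select(set(atom_names) if atom_names else None)
    sel_b = b.select(set(atom_names) if atom_names else None)
    key = lambda at: (at.chain, at.res_num, at.atom_name)
    map_b = {key(at): at for at in sel_b.atoms}
    pa, pb = [], []
    for at in sel_a.atoms:
        other = map_b.get(key(at))
        if other is not None:
            pa.append([at.x, at.y, at.z])
            pb.append([other.x, other.y, other.z])
    if len(pa) != len(sel_a.atoms) or len(pa) != len(sel_b.atoms):
        raise ValueError(
            f"selections do not match: {len(sel_a.atoms)} vs {len(sel_b.atoms)} atoms, "
            f"{len(pa)} shared keys"
        )
    return kabsch_rmsd(np.array(pa), np.array(pb))


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1, norm2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if norm1 < 1e-9 or norm2 < 1e-9:
        raise ValueError("degenerate (collinear) geometry")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = -math.degrees(math.atan2(y, x))  # IUPAC sign convention
    return 180.0 if ang == -180.0 else ang


def backbone_dihedrals(coords: CoordinateSet) -> list[tuple[str, int, float | None, float | None]]:
    """Phi/psi torsions per residue: (chain, residue number, phi, psi).

    phi = C(i-1)-N-CA-C, psi = N-CA-C-N(i+1); chain termini yield None for
    the undefined angle.  Residues missing backbone atoms are skipped with
    a warning.
    """
    by_res: dict[tuple[str, int], dict[str, Atom]] = {}
    for a in coords.atoms:
        by_res.setdefault((a.chain, a.res_num), {})[a.atom_name] = a
    chains: dict[str, list[int]] = {}
    for chain, num in by_res:
        chains.setdefault(chain, []).append(num)
    out = []
    for chain, nums in chains.items():
        nums = sorted(nums)
        complete = []
        for num in nums:
            res = by_res[(chain, num)]
            if all(n in res for n in ("N", "CA", "C")):
                complete.append(num)
            else:
                warnings.warn(f"residue {chain}{num} missing backbone atoms; skipped")
        pos = lambda num, name: [getattr(by_res[(chain, num)][name], ax) for ax in "xyz"]
        for idx, num in enumerate(complete):
            prev_num = complete[idx - 1] if idx > 0 and complete[idx - 1] == num - 1 else None
            next_num = (
                complete[idx + 1]
                if idx + 1 < len(complete) and complete[idx + 1] == num + 1
                else None
            )
            phi = (
                _dihedral(pos(prev_num, "C"), pos(num, "N"), pos(num, "CA"), pos(num, "C"))
                if prev_num is not None
                else None
            )
            psi = (
                _dihedral(pos(num, "N"), pos(num, "CA"), pos(num, "C"), pos(next_num, "N"))
                if next_num is not None
                else None
            )
            out.append((chain, num, phi, psi))
    return out


#: Coarse favored Ramachandran regions as (phi_lo, phi_hi, psi_lo, psi_hi)
#: rectangles: right-handed alpha, beta (two psi wings), left-handed alpha.
DEFAULT_FAVORED_BOXES: tuple[tuple[float, float, float, float], ...] = (
    (-160.0, -20.0, -120.0, 50.0),   # alpha-R
    (-180.0, -45.0, 90.0, 180.0),    # beta
    (-180.0, -45.0, -180.0, -150.0), # beta (wrapped psi)
    (20.0, 100.0, -20.0, 90.0),      # alpha-L
)


def favored_fraction(
    dihedrals: list[tuple[str, int, float | None, float | None]],
    region_map=None,
) -> float:
    """Percent of defined (phi, psi) pairs inside favored regions.

    ``region_map`` may be a callable (phi, psi) -> bool; by default the
    coarse rectangular boxes in :data:`DEFAULT_FAVORED_BOXES` are used.
    Residues with an undefined phi or psi (termini) are excluded from the
    denominator.
    """
    if region_map is None:
        region_map = lambda phi, psi: any(
            lo_f <= phi <= hi_f and lo_p <= psi <= hi_p
            for lo_f, hi_f, lo_p, hi_p in DEFAULT_FAVORED_BOXES
        )
    pairs = [(phi, psi) for _, _, phi, psi in dihedrals if phi is not None and psi is not None]
    if not pairs:
        raise ValueError("no defined (phi, psi) pairs")
    inside = sum(1 for phi, psi in pairs if region_map(phi, psi))
    return 100.0 * inside / len(pairs)
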