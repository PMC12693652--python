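"""Packaged reference tables: the published CaMBD window/codon grid, the
ipTM replicate grid with printed confidence bounds, the binding-energy
grid, the FoldX-style wild-type/mutant energies, and the default
substitution plan.  These static fixtures drive the golden checks and the
analysis drivers; the random generators live in :mod:`cambd.synth`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .motifs import CaMBDWindow
from .variants import SubstitutionPlan

__all__ = [
    "load_codon_grid",
    "load_isoform_windows",
    "load_substitution_plan",
    "load_iptm_table",
    "load_ddg_table",
    "load_foldx_dg_text",
    "load_wt_map_path",
    "PMCA4B_NUMBERING_OFFSET",
]

#: window position 1 corresponds to residue 1093 in PMCA4b numbering
PMCA4B_NUMBERING_OFFSET = 1092

_DATA = resources.files("cambd") / "data"


def load_codon_grid() -> pd.DataFrame:
    """Isoform x window-position codon grid (columns T01..T18)."""
    with resources.as_file(_DATA / "table1_windows.tsv") as p:
        return pd.read_csv(p, sep="\t")


def load_isoform_windows() -> list[CaMBDWindow]:
    """One CaMBD window per isoform, built from the packaged codon grid."""
    grid = load_codon_grid()
    codon_cols = [f"T{i:02d}" for i in range(1, 19)]
    windows = []
    for _, row in grid.iterrows():
        codons = [row[c] for c in codon_cols]
        from .motifs import translate_cds

        windows.append(
            CaMBDWindow(
                member_isoforms=[row["isoform"]],
                residues=translate_cds("".join(codons)),
                codons=codons,
                reference_numbering_offset=PMCA4B_NUMBERING_OFFSET,
            )
        )
    return windows


def load_substitution_plan() -> SubstitutionPlan:
    with resources.as_file(_DATA / "substitution_plan.yaml") as p:
        return SubstitutionPlan.from_yaml(p)


def load_iptm_table() -> pd.DataFrame:
    """Replicate ipTM grid (m0..m4) with printed interval bounds."""
    with resources.as_file(_DATA / "table2_iptm.tsv") as p:
        return pd.read_csv(p, sep="\t")


def load_ddg_table() -> pd.DataFrame:
    """Binding-energy change grid: 70 evaluated + 6 literature records."""
    with resources.as_file(_DATA / "table3_ddg.tsv") as p:
        return pd.read_csv(p, sep="\t")


def load_foldx_dg_text() -> str:
    """AnalyseComplex-style wild-type/mutant interaction energies."""
    return (_DATA / "foldx_dg.tsv").read_text()


def load_wt_map_path():
    """Context manager yielding the packaged wild-type pairing YAML path."""
    return resources.as_file(_DATA / "wt_map.yaml")
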