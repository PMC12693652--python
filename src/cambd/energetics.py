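"""Binding-energy differences and their classification.

For every substituted complex, DDG = DG_substituted - DG_wildtype
(kcal/mol); positive values mean less favorable binding.  A change only
counts as an effect when its magnitude strictly exceeds the method's error
band: +/-1.7 kcal/mol for FoldX-style energies (twice the method's 0.85
kcal/mol error) and +/-1.5 kcal/mol for MutaBind2-style predictions (the
server's own criterion).  Values at or inside the band are "within error".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "CUTOFFS",
    "BindingEnergy",
    "DdgClassification",
    "CohortSummary",
    "compute_ddg",
    "classify_ddg",
    "summarize_cohort",
    "parse_foldx_output",
    "ddg_from_dg",
    "load_wt_map",
]

#: method -> |DDG| cutoff (kcal/mol) below/at which a change is within error
CUTOFFS = {"foldx": 1.7, "mutabind2": 1.5}


@dataclass
class BindingEnergy:
    complex_id: str
    variant_label: str = "WT"
    method: str = "foldx"
    dg: float | None = None
    ddg: float | None = None

    def __post_init__(self) -> None:
        if self.dg is None and self.ddg is None:
            raise ValueError("need at least one of dg/ddg")
        if self.method not in CUTOFFS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class DdgClassification:
    complex_id: str
    substitution: str
    method: str
    ddg: float
    cutoff: float
    label: str  # weakening | strengthening | within_error


@dataclass
class CohortSummary:
    n_total: int
    n_within: int
    n_weakening: int
    n_strengthening: int
    by_method: dict[str, dict[str, int]] = field(default_factory=dict)


def compute_ddg(dg_sbs: float, dg_wt: float) -> float:
    """DG_substituted - DG_wildtype; positive = weaker binding."""
    if not (math.isfinite(dg_sbs) and math.isfinite(dg_wt)):
        raise ValueError("energies must be finite")
    return dg_sbs - dg_wt


def classify_ddg(
    ddg: float, method: str, complex_id: str = "", substitution: str = ""
) -> DdgClassification:
    """Label a binding-energy change against its method-specific cutoff.

    The boundary is strict: |ddg| == cutoff is within error; an effect
    requires the change to exceed the band (so 1.72 at the 1.7 FoldX
    cutoff is weakening).
    """
    if method not in CUTOFFS:
        raise ValueError(f"unknown method {method!r}")
    cutoff = CUTOFFS[method]
    if ddg > cutoff:
        label = "weakening"
    elif ddg < -cutoff:
        label = "strengthening"
    else:
        label = "within_error"
    return DdgClassification(
        complex_id=complex_id, substitution=substitution, method=method,
        ddg=ddg, cutoff=cutoff, label=label,
    )


def summarize_cohort(classifications: list[DdgClassification]) -> CohortSummary:
    """Totals and per-method counts over a set of classifications."""
    by_method: dict[str, dict[str, int]] = {}
    counts = {"weakening": 0, "strengthening": 0, "within_error": 0}
    for c in classifications:
        counts[c.label] += 1
        m = by_method.setdefault(
            c.method, {"weakening": 0, "strengthening": 0, "within_error": 0}
        )
        m[c.label] += 1
    return CohortSummary(
        n_total=len(classifications),
        n_within=counts["within_error"],
        n_weakening=counts["weakening"],
        n_strengthening=counts["strengthening"],
        by_method=by_method,
    )


def parse_foldx_output(source: str | Path | list[str]) -> list[BindingEnergy]:
    """Parse an AnalyseComplex-style tab-separated summary into DG records.

    Tolerant of header naming (any column containing "interaction energy",
    case-insensitive, or named "dG"); strict on numeric parsing.  One
    record per line, order preserved.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        lines = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError("empty FoldX output")
    header = lines[0].split("\t")
    energy_col = None
    for i, name in enumerate(header):
        if "interaction energy" in name.lower() or name.strip() in ("dG", "dg"):
            energy_col = i
            break
    if energy_col is None:
        raise ValueError("no interaction-energy column in header")
    records = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) <= energy_col:
            raise ValueError(f"short line: {ln!r}")
        try:
            dg = float(cells[energy_col])
        except ValueError as err:
            raise ValueError(f"non-numeric energy {cells[energy_col]!r}") from err
        records.append(BindingEnergy(complex_id=cells[0], dg=dg, method="foldx"))
    return records


def load_wt_map(path: str | Path) -> dict[str, str]:
    """Mutant-complex -> wild-type-complex pairing (explicit, never inferred)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in raw.items()}


def ddg_from_dg(records: list[BindingEnergy], wt_map: dict[str, str]) -> pd.DataFrame:
    """DDG for every mutant record with a mapped wild type.

    Returns a table with complex_id, wt_id, dg_sbs, dg_wt and ddg; raises
    when a mapped wild type has no DG record.
    """
    dg_by_id = {r.complex_id: r.dg for r in records if r.dg is not None}
    rows = []
    for mut_id, wt_id in wt_map.items():
        if mut_id not in dg_by_id:
            raise ValueError(f"no DG record for mutant {mut_id}")
        if wt_id not in dg_by_id:
            raise ValueError(f"no DG record for wild type {wt_id}")
        rows.append(
            {
                "complex_id": mut_id,
                "wt_id": wt_id,
                "dg_sbs": dg_by_id[mut_id],
                "dg_wt": dg_by_id[wt_id],
                "ddg": compute_ddg(dg_by_id[mut_id], dg_by_id[wt_id]),
            }
        )
    return pd.DataFrame(rows)
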