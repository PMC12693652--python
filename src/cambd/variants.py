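"""Single-nucleotide codon-edit enumeration and substitution planning.

Candidate missense changes in the CaMBD are restricted to those reachable
by editing one base of a codon — by default the second base, where the
genetic code is least degenerate and a single change almost always alters
the encoded residue.  A substitution plan maps motif positions to target
codons; realizing the plan across the deduplicated isoform window groups
yields the set of amino-acid substitution classes the screen evaluates
(L5R, N6I, I8T, V14E/D, F18S with the shipped defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio.Data.CodonTable import standard_dna_table

from .motifs import CaMBDWindow

__all__ = [
    "STOP",
    "CodonEdit",
    "SubstitutionClass",
    "SubstitutionPlan",
    "RealizedSubstitution",
    "PlanRealization",
    "translate_codon",
    "enumerate_edits",
    "realize_plan",
    "distinct_classes",
]

STOP = "*"
BASES = "acgt"

_CODON_TO_AA = {codon.lower(): aa for codon, aa in standard_dna_table.forward_table.items()}
_CODON_TO_AA.update({codon.lower(): STOP for codon in standard_dna_table.stop_codons})


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; ``*`` for a stop."""
    codon = codon.lower()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return _CODON_TO_AA[codon]


@dataclass(frozen=True)
class CodonEdit:
    """One single-base codon change and the substitution it realizes."""

    codon_before: str
    codon_position: int  # 1-3
    base_after: str
    codon_after: str
    aa_before: str
    aa_after: str
    edit_class: str  # synonymous | missense | nonsense


@dataclass(frozen=True, order=True)
class SubstitutionClass:
    """An amino-acid substitution at a motif position, e.g. V14E."""

    motif_position: int
    aa_before: str
    aa_after: str

    def __post_init__(self) -> None:
        if self.aa_before == self.aa_after:
            raise ValueError("substitution must change the residue")
        if STOP in (self.aa_before, self.aa_after):
            raise ValueError("stop codons do not form a substitution class")

    @property
    def label(self) -> str:
        return f"{self.aa_before}{self.motif_position}{self.aa_after}"


@dataclass
class SubstitutionPlan:
    """Motif position -> target codons, all reached by one base edit."""

    entries: dict[int, list[str]]
    codon_position: int = 2

    def __post_init__(self) -> None:
        if self.codon_position not in (1, 2, 3):
            raise ValueError("codon_position must be 1, 2 or 3")
        self.entries = {
            int(pos): [c.lower() for c in codons] for pos, codons in self.entries.items()
        }
        for pos, codons in self.entries.items():
            for c in codons:
                translate_codon(c)  # validity check

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubstitutionPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(entries=raw["entries"], codon_position=raw.get("codon_position", 2))


@dataclass(frozen=True)
class RealizedSubstitution:
    group_label: str
    substitution: SubstitutionClass
    edit: CodonEdit


@dataclass
class PlanRealization:
    realized: list[RealizedSubstitution]
    unmatched: list[tuple[str, int, str]] = field(default_factory=list)  # (group, position, codon)


def enumerate_edits(codon: str, codon_position: int = 2) -> list[CodonEdit]:
    """The three single-base edits of ``codon`` at ``codon_position``.

    Each edit is classified by translation as synonymous, missense or
    nonsense.
    """
    codon = codon.lower()
    aa_before = translate_codon(codon)
    if codon_position not in (1, 2, 3):
        raise ValueError("codon_position must be 1, 2 or 3")
    i = codon_position - 1
    edits = []
    for base in BASES:
        if base == codon[i]:
            continue
        after = codon[:i] + base + codon[i + 1 :]
        aa_after = translate_codon(after)
        if aa_after == STOP:
            edit_class = "nonsense"
        elif aa_after == aa_before:
            edit_class = "synonymous"
        else:
            edit_class = "missense"
        edits.append(
            CodonEdit(
                codon_before=codon,
                codon_position=codon_position,
                base_after=base,
                codon_after=after,
                aa_before=aa_before,
                aa_after=aa_after,
                edit_class=edit_class,
            )
        )
    return edits


def _hamming(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def realize_plan(windows: list[CaMBDWindow], plan: SubstitutionPlan) -> PlanRealization:
    """Apply a substitution plan across window groups.

    For each group and planned motif position, the target codon differing
    from the group's codon at exactly the plan's codon position is applied
    and translated; plan entries where no target codon is a single-edit
    neighbour of the group codon are reported as unmatched.  A target that
    differs at a *different* single position than configured is an error.
    """
    out = PlanRealization(realized=[])
    pos_idx = plan.codon_position - 1
    for w in windows:
        if w.codons is None:
            raise ValueError(f"group {w.label} carries no codons")
        for motif_pos, targets in sorted(plan.entries.items()):
            codon = w.codons[motif_pos - 1]
            matched = False
            for target in targets:
                diff = _hamming(codon, target)
                if diff == [pos_idx]:
                    matched = True
                    aa_before = translate_codon(codon)
                    aa_after = translate_codon(target)
                    if aa_after == STOP or aa_after == aa_before:
                        continue
                    edit = CodonEdit(
                        codon_before=codon,
                        codon_position=plan.codon_position,
                        base_after=target[pos_idx],
                        codon_after=target,
                        aa_before=aa_before,
                        aa_after=aa_after,
                        edit_class="missense",
                    )
                    out.realized.append(
                        RealizedSubstitution(
                            group_label=w.label,
                            substitution=SubstitutionClass(motif_pos, aa_before, aa_after),
                            edit=edit,
                        )
                    )
                elif len(diff) == 1:
                    raise ValueError(
                        f"plan target {target} for {w.label} position {motif_pos} edits codon "
                        f"position {diff[0] + 1}, not the configured {plan.codon_position}"
                    )
            if not matched:
                out.unmatched.append((w.label, motif_pos, codon))
    return out


def distinct_classes(realized: list[RealizedSubstitution]) -> set[SubstitutionClass]:
    """Deduplicated substitution classes over all groups."""
    return {r.substitution for r in realized}
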