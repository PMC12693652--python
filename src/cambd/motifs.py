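"""Delimitation of the calmodulin-binding domain (CaMBD) in PMCA isoforms.

The plasma-membrane Ca2+-ATPase (PMCA) carries a C-terminal autoinhibitory
region with an 18-residue calmodulin-binding window bounded by two aromatic
anchors (W at position 1, F at position 18; PMCA4b numbering 1093-1110).
This module locates that window in full-length isoform sequences by scanning
for the C28 reference peptide of PMCA4b, extracts the window together with
its codons, and collapses windows that are identical across splice variants
of the same pump.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "MotifLibrary",
    "IsoformRecord",
    "CaMBDWindow",
    "MotifHit",
    "MotifNotFoundError",
    "translate_cds",
    "scan_for_motif",
    "extract_window",
    "find_cambd",
    "dedup_windows",
    "group_label",
    "read_isoform_fasta",
    "windows_to_table",
    "WINDOW_LENGTH",
    "C28_ANCHOR_OFFSET",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = set("acgt")

#: length of the calmodulin-binding window delimited by the W1/F18 anchors
WINDOW_LENGTH = 18
#: 0-based offset of the W1 anchor inside the C28 reference peptide
C28_ANCHOR_OFFSET = 7


class MotifNotFoundError(ValueError):
    """No window of the scanned sequence reached the identity threshold."""


@dataclass(frozen=True)
class MotifLibrary:
    """Reference peptides used to locate and delimit the CaMBD.

    ``c28`` is the 28-residue PMCA4b peptide present in the NMR complex
    2KNE; ``pattern1``/``pattern2`` are consensus subsequences delimiting
    the N- and C-terminal halves of the window.
    """

    c28: str = "LRRGQILWFRGLNRIQTQIKVVKAFHSS"
    pattern1: str = "GQILWFRGLNRIQTQ"
    pattern2: str = "IRVVNAFR"


@dataclass
class IsoformRecord:
    """One pump isoform/splice variant: protein sequence plus optional CDS."""

    gene_symbol: str
    isoform_label: str
    accession: str
    protein_seq: str
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        self.protein_seq = self.protein_seq.upper()
        if not self.protein_seq:
            raise ValueError("protein_seq must be non-empty")
        bad = set(self.protein_seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid amino acids in {self.isoform_label}: {sorted(bad)}")
        if self.cds_seq is not None:
            self.cds_seq = self.cds_seq.lower()
            n = 3 * len(self.protein_seq)
            if len(self.cds_seq) not in (n, n + 3):
                raise ValueError(
                    f"CDS length {len(self.cds_seq)} does not match protein "
                    f"length {len(self.protein_seq)} for {self.isoform_label}"
                )
            if translate_cds(self.cds_seq[:n]) != self.protein_seq:
                raise ValueError(f"CDS does not translate to protein for {self.isoform_label}")

    def codon(self, position: int) -> str:
        """Codon for the 1-based protein ``position``."""
        if self.cds_seq is None:
            raise ValueError("record has no CDS")
        return self.cds_seq[3 * (position - 1) : 3 * position]


@dataclass
class CaMBDWindow:
    """An 18-residue CaMBD window with codons and provenance.

    ``reference_numbering_offset`` maps window position 1 to a reference
    residue number (1092 puts W1 at 1093, the PMCA4b convention).
    """

    member_isoforms: list[str]
    residues: str
    codons: list[str] | None = None
    start_pos_protein: int | None = None
    reference_numbering_offset: int | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) != WINDOW_LENGTH:
            raise ValueError(f"window must have {WINDOW_LENGTH} residues")
        if self.codons is not None:
            self.codons = [c.lower() for c in self.codons]
            if len(self.codons) != WINDOW_LENGTH:
                raise ValueError("need one codon per window residue")
            for codon, aa in zip(self.codons, self.residues):
                if translate_cds(codon) != aa:
                    raise ValueError(f"codon {codon} does not encode {aa}")

    @property
    def label(self) -> str:
        return group_label(self.member_isoforms)


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based
    identity: float


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    A single terminal stop codon is accepted and dropped; an internal stop
    raises ``ValueError``, as do non-triplet lengths and non-ACGT letters.
    """
    cds = cds.lower()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    bad = set(cds) - NUCLEOTIDES
    if bad:
        raise ValueError(f"invalid nucleotides: {sorted(bad)}")
    if not cds:
        return ""
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon")
    return protein


def scan_for_motif(protein: str, motif: str, min_identity: float = 0.6) -> MotifHit:
    """Best ungapped sliding-window match of ``motif`` in ``protein``.

    Identity is matches/len(motif); the leftmost window attaining the
    maximal identity wins. Raises :class:`MotifNotFoundError` when no
    window reaches ``min_identity``.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    protein = protein.upper()
    motif = motif.upper()
    m = len(motif)
    best_start, best_identity = None, -1.0
    for start in range(len(protein) - m + 1):
        matches = sum(1 for a, b in zip(protein[start : start + m], motif) if a == b)
        identity = matches / m
        if identity > best_identity:
            best_start, best_identity = start, identity
    if best_start is None or best_identity < min_identity:
        raise MotifNotFoundError(
            f"motif not found at identity >= {min_identity} (best {max(best_identity, 0.0):.2f})"
        )
    return MotifHit(start=best_start + 1, identity=best_identity)


def extract_window(
    record: IsoformRecord,
    anchor_start: int,
    strict_anchors: bool = False,
    reference_numbering_offset: int | None = None,
) -> CaMBDWindow:
    """Slice the 18-residue window starting at 1-based ``anchor_start``.

    ``anchor_start`` must point at the W aligned to C28 position 8.  When
    the record carries a CDS the matching codons are sliced alongside.  A
    window whose first/last residues are not W/F warns by default and
    raises in strict mode (ortholog windows may deviate at the anchors).
    """
    if anchor_start < 1 or anchor_start + WINDOW_LENGTH - 1 > len(record.protein_seq):
        raise ValueError(
            f"window [{anchor_start}, {anchor_start + WINDOW_LENGTH - 1}] exceeds "
            f"protein bounds (len {len(record.protein_seq)})"
        )
    residues = record.protein_seq[anchor_start - 1 : anchor_start - 1 + WINDOW_LENGTH]
    if residues[0] != "W" or residues[-1] != "F":
        msg = f"{record.isoform_label}: window anchors are {residues[0]}1/{residues[-1]}18, expected W1/F18"
        if strict_anchors:
            raise ValueError(msg)
        warnings.warn(msg)
    codons = None
    if record.cds_seq is not None:
        codons = [record.codon(anchor_start + i) for i in range(WINDOW_LENGTH)]
    return CaMBDWindow(
        member_isoforms=[record.isoform_label],
        residues=residues,
        codons=codons,
        start_pos_protein=anchor_start,
        reference_numbering_offset=reference_numbering_offset,
    )


def find_cambd(
    record: IsoformRecord,
    library: MotifLibrary | None = None,
    min_identity: float = 0.6,
    strict_anchors: bool = False,
) -> CaMBDWindow:
    """Scan for the C28 reference peptide and extract the anchored window."""
    library = library or MotifLibrary()
    hit = scan_for_motif(record.protein_seq, library.c28, min_identity)
    return extract_window(record, hit.start + C28_ANCHOR_OFFSET, strict_anchors=strict_anchors)


def group_label(members: list[str]) -> str:
    """Join member isoform labels, keeping a shared prefix once.

    ["PMCA2a", "PMCA2b", "PMCA3b"] -> "PMCA2a_2b_3b" (the conventional
    group naming); labels without the shared prefix are joined verbatim.
    """
    if not members:
        raise ValueError("empty group")
    first = members[0]
    prefix = "".join(c for c in first if not (c.isdigit() or c.islower()))
    parts = [first]
    for m in members[1:]:
        parts.append(m.removeprefix(prefix) if prefix and m.startswith(prefix) else m)
    return "_".join(parts)


def dedup_windows(windows: list[CaMBDWindow]) -> list[CaMBDWindow]:
    """Merge windows with identical residue strings into one group each.

    Splice variants of the same pump frequently share an identical CaMBD;
    redundant windows are collapsed, concatenating member lists in input
    order.  The merged window carries the first member's codons.
    """
    groups: dict[str, CaMBDWindow] = {}
    for w in windows:
        if len(w.residues) != WINDOW_LENGTH:
            raise ValueError("all windows must be 18 residues")
        if w.residues in groups:
            groups[w.residues].member_isoforms.extend(w.member_isoforms)
        else:
            groups[w.residues] = CaMBDWindow(
                member_isoforms=list(w.member_isoforms),
                residues=w.residues,
                codons=list(w.codons) if w.codons is not None else None,
                start_pos_protein=w.start_pos_protein,
                reference_numbering_offset=w.reference_numbering_offset,
            )
    return list(groups.values())


def read_isoform_fasta(protein_path: str | Path, cds_path: str | Path | None = None) -> list[IsoformRecord]:
    """Read isoforms from multi-FASTA with ``accession|gene|isoform`` headers."""
    cds_by_label: dict[str, str] = {}
    if cds_path is not None:
        for rec in SeqIO.parse(str(cds_path), "fasta"):
            _, _, label = _parse_header(rec.id)
            cds_by_label[label] = str(rec.seq)
    records = []
    for rec in SeqIO.parse(str(protein_path), "fasta"):
        accession, gene, label = _parse_header(rec.id)
        records.append(
            IsoformRecord(
                gene_symbol=gene,
                isoform_label=label,
                accession=accession,
                protein_seq=str(rec.seq),
                cds_seq=cds_by_label.get(label),
            )
        )
    return records


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise ValueError(f"FASTA header {header!r} is not 'accession|gene|isoform'")
    return parts[0], parts[1], parts[2]


def windows_to_table(windows: list[CaMBDWindow]) -> pd.DataFrame:
    """Window groups as a table (one row per group)."""
    return pd.DataFrame(
        {
            "group_label": [w.label for w in windows],
            "members": [",".join(w.member_isoforms) for w in windows],
            "residues": [w.residues for w in windows],
            "codons": [",".join(w.codons) if w.codons else "" for w in windows],
            "start_pos": [w.start_pos_protein for w in windows],
            "offset": [w.reference_numbering_offset for w in windows],
        }
    )
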