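"""Seeded synthetic fixtures emulating every external input of the screen.

Each generator is a pure function of (seed, parameters) and draws from an
independent substream — ``numpy.random.default_rng([seed, stream])`` — so
adding one fixture never shifts another.  The generators emulate only the
statistical and file-format surface the pipeline consumes: isoform
families sharing a divergently mutated 18-residue motif with a consistent
CDS, Gaussian ipTM replicate grids, binding-energy tables with planted
effect proportions, and gene-disease association exports with controlled
score/type/polygenicity structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .energetics import CUTOFFS
from .motifs import IsoformRecord

__all__ = [
    "FixtureSpec",
    "gen_isoform_family",
    "gen_iptm_replicates",
    "gen_energy_tables",
    "gen_gda_table",
    "write_family_fasta",
    "ci_coverage",
    "DEFAULT_MOTIF",
]

#: PMCA4b CaMBD window (C28 positions 8-25), the family consensus
DEFAULT_MOTIF = "WFRGLNRIQTQIKVVKAF"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYNONYMOUS.setdefault(_aa, []).append(_codon.lower())
for _aa in _SYNONYMOUS:
    _SYNONYMOUS[_aa].sort()

# Substream ids, one per generator family.
_STREAM_FAMILY, _STREAM_IPTM, _STREAM_ENERGY, _STREAM_GDA = 11, 13, 17, 19


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass
class FixtureSpec:
    """Conditions the synthetic inputs emulate.

    Defaults mirror the real study family: 11 isoforms over 4 genes
    sharing the PMCA4b window, ~15% per-site divergence (the observed
    variability is confined to the window's C-terminal half), 5 ipTM
    replicates per complex near 0.65 with sd 0.03, and a 70-record
    energy cohort of which ~20% is within error.
    """

    seed: int = 0
    n_isoforms: int = 11
    motif: str = DEFAULT_MOTIF
    divergence: float = 0.15
    flank_length: int = 30
    iptm_mu: float = 0.65
    iptm_sigma: float = 0.03
    energy_effect_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # weaken, strengthen, within
    n_energy: int = 70
    n_gda: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")
        if abs(sum(self.energy_effect_mix) - 1.0) > 1e-9:
            raise ValueError("energy_effect_mix must sum to 1")
        if self.iptm_sigma < 0:
            raise ValueError("iptm_sigma must be >= 0")


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _SYNONYMOUS[aa][rng.integers(len(_SYNONYMOUS[aa]))] for aa in protein
    )


def gen_isoform_family(spec: FixtureSpec) -> list[IsoformRecord]:
    """Isoform records embedding a per-site mutated motif in random flanks.

    The W1/F18 anchors are never mutated; interior sites flip to a random
    different residue with probability ``divergence``.  The CDS is a
    seeded uniform choice among synonymous codons, so it always
    round-trips to the protein.
    """
    rng = _rng(spec.seed, _STREAM_FAMILY)
    records = []
    genes = ["ATP2B1", "ATP2B2", "ATP2B3", "ATP2B4"]
    for i in range(spec.n_isoforms):
        window = list(spec.motif)
        for j in range(1, len(window) - 1):
            if rng.random() < spec.divergence:
                choices = [a for a in AMINO_ACIDS if a != window[j]]
                window[j] = choices[rng.integers(len(choices))]
        flank5 = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(spec.flank_length))
        flank3 = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(spec.flank_length))
        protein = flank5 + "".join(window) + flank3
        records.append(
            IsoformRecord(
                gene_symbol=genes[i % len(genes)],
                isoform_label=f"SYN{i + 1:02d}",
                accession=f"SYN_{spec.seed}_{i + 1:02d}",
                protein_seq=protein,
                cds_seq=_reverse_translate(protein, rng),
            )
        )
    return records


def write_family_fasta(
    records: list[IsoformRecord], protein_path: str | Path, cds_path: str | Path | None = None
) -> None:
    """Write protein (and optionally CDS) multi-FASTA with pipe headers."""
    with open(protein_path, "w") as fh:
        for r in records:
            fh.write(f">{r.accession}|{r.gene_symbol}|{r.isoform_label}\n{r.protein_seq}\n")
    if cds_path is not None:
        with open(cds_path, "w") as fh:
            for r in records:
                fh.write(f">{r.accession}|{r.gene_symbol}|{r.isoform_label}\n{r.cds_seq}\n")


def gen_iptm_replicates(
    seed: int, mu: float = 0.65, sigma: float = 0.03, n: int = 5, n_complexes: int = 7
) -> pd.DataFrame:
    """Gaussian ipTM replicates per complex, clamped to [0, 1]."""
    rng = _rng(seed, _STREAM_IPTM)
    data = np.clip(rng.normal(mu, sigma, size=(n_complexes, n)), 0.0, 1.0)
    df = pd.DataFrame(data, columns=[f"m{k}" for k in range(n)])
    df.insert(0, "complex_id", [f"CPX{i + 1:04d}" for i in range(n_complexes)])
    return df


def ci_coverage(
    seed: int,
    mu: float = 0.65,
    sigma: float = 0.03,
    n_sets: int = 2000,
    n: int = 5,
    level: float = 0.95,
) -> float:
    """Fraction of Student-t CIs covering the true mean over replicate sets."""
    from .confidence import summarize_iptm

    df = gen_iptm_replicates(seed, mu, sigma, n=n, n_complexes=n_sets)
    cols = [c for c in df.columns if c.startswith("m")]
    hits = 0
    for _, row in df.iterrows():
        s = summarize_iptm([row[c] for c in cols], level=level)
        hits += s.ci_lo <= mu <= s.ci_hi
    return hits / n_sets


@dataclass
class EnergyTables:
    foldx_text: str
    mutabind: pd.DataFrame
    truth: pd.DataFrame


def gen_energy_tables(seed: int, spec: FixtureSpec | None = None) -> EnergyTables:
    """FoldX-style DG lines and MutaBind2-style DDG rows with truth labels.

    Class counts follow the planted mix exactly (largest-remainder
    apportionment); DDG magnitudes are drawn uniformly outside (effects)
    or inside (within-error) the method's cutoff band, so recovered labels
    equal the planted ones by construction.
    """
    spec = spec or FixtureSpec(seed=seed)
    rng = _rng(seed, _STREAM_ENERGY)
    n = spec.n_energy
    raw = [m * n for m in spec.energy_effect_mix]
    counts = [int(x) for x in raw]
    rema = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in rema[: n - sum(counts)]:
        counts[i] += 1
    labels = (
        ["weakening"] * counts[0] + ["strengthening"] * counts[1] + ["within_error"] * counts[2]
    )
    rng.shuffle(labels)
    methods = ["foldx" if i % 2 == 0 else "mutabind2" for i in range(n)]
    rows = []
    for i, (label, method) in enumerate(zip(labels, methods)):
        cutoff = CUTOFFS[method]
        if label == "weakening":
            ddg = rng.uniform(cutoff + 0.1, 10.0)
        elif label == "strengthening":
            ddg = -rng.uniform(cutoff + 0.1, 10.0)
        else:
            ddg = rng.uniform(-cutoff, cutoff)
        rows.append(
            {"complex_id": f"CPX{i + 1:04d}", "method": method, "ddg": round(ddg, 2), "label": label}
        )
    truth = pd.DataFrame(rows)

    foldx = truth[truth["method"] == "foldx"]
    lines = ["Pdb\tGroup1\tGroup2\tInteraction Energy"]
    for _, r in foldx.iterrows():
        dg_wt = rng.uniform(-65.0, -45.0)
        lines.append(f"{r.complex_id}_WT.pdb\tA\tB\t{dg_wt:.2f}")
        lines.append(f"{r.complex_id}_SBS.pdb\tA\tB\t{dg_wt + r.ddg:.2f}")
    mutabind = truth[truth["method"] == "mutabind2"][["complex_id", "ddg"]].copy()
    mutabind.insert(1, "chain", "B")
    mutabind.insert(2, "mutation", "VA14E")
    return EnergyTables(foldx_text="\n".join(lines) + "\n", mutabind=mutabind, truth=truth)


def gen_gda_table(seed: int, n_gda: int = 40) -> pd.DataFrame:
    """Gene-disease association export with controlled structure.

    Scores are uniform on [0, 1]; association types cycle through the
    retained and discarded classes; linked-gene counts cycle through
    values spanning all polygenicity classes and both strata.
    """
    if n_gda < 0:
        raise ValueError("n_gda must be >= 0")
    rng = _rng(seed, _STREAM_GDA)
    genes = ["ATP2B1", "ATP2B2", "ATP2B3", "ATP2B4"]
    types = ["CausalMutation", "GeneticVariation", "other"]
    ngenes_cycle = [1, 2, 7, 30, 31, 120]
    rows = []
    for i in range(n_gda):
        rows.append(
            {
                "gene": genes[i % 4],
                "disease_id": f"D{i + 1:05d}",
                "disease_name": f"synthetic disease {i + 1}",
                "score_gda": round(float(rng.uniform()), 3),
                "association_type": types[int(rng.integers(3))],
                "n_genes_disease": ngenes_cycle[i % len(ngenes_cycle)],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "disease_id", "disease_name", "score_gda",
            "association_type", "n_genes_disease",
        ],
    )
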