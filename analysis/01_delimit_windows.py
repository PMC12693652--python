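"""Delimit the CaM-binding window across PMCA isoforms and collapse
redundant splice variants.

Embeds each isoform's published 18-codon window in a synthetic full-length
context (C28 scaffold plus seeded random flanks, CDS consistent with the
window codons), scans for the C28 reference peptide, extracts the anchored
window, and deduplicates.  Writes results/windows.tsv.
"""

import sys
from pathlib import Path

import numpy as np

from cambd.motifs import IsoformRecord, MotifLibrary, dedup_windows, find_cambd, windows_to_table
from cambd.reference import load_codon_grid
from cambd.synth import _reverse_translate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def build_records(seed: int) -> list[IsoformRecord]:
    """Isoform records with the true window codons in a synthetic context."""
    c28 = MotifLibrary().c28
    grid = load_codon_grid()
    rng = np.random.default_rng([seed, 1])
    records = []
    for _, row in grid.iterrows():
        codons = [row[f"T{i:02d}"] for i in range(1, 19)]
        from cambd.motifs import translate_cds

        window = translate_cds("".join(codons))
        flank5, flank3 = "GSGSGS" + c28[:7], c28[25:] + "GSGSGS"
        protein = flank5 + window + flank3
        cds = (
            _reverse_translate(flank5, rng) + "".join(codons) + _reverse_translate(flank3, rng)
        )
        records.append(
            IsoformRecord(row["gene"], row["isoform"], row["accession"], protein, cds)
        )
    return records


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = build_records(SEED)
    windows = [find_cambd(rec) for rec in records]
    groups = dedup_windows(windows)
    table = windows_to_table(groups)
    table.to_csv(OUT / "windows.tsv", sep="\t", index=False)
    print(f"{len(records)} isoforms -> {len(groups)} non-redundant window groups:")
    for g in groups:
        print(f"  {g.label:<14} {g.residues}")
    print(f"wrote {OUT / 'windows.tsv'}")


if __name__ == "__main__":
    main()
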