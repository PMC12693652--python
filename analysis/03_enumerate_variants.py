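"""Realize the second-position substitution plan across the window groups.

Applies the packaged plan (positions 5, 6, 8, 14, 18) to the deduplicated
isoform windows and tabulates the realized single-nucleotide substitution
classes.  Writes results/substitutions.tsv.
"""

from pathlib import Path

import pandas as pd

from cambd.motifs import dedup_windows
from cambd.reference import load_isoform_windows, load_substitution_plan
from cambd.variants import distinct_classes, realize_plan

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    groups = dedup_windows(load_isoform_windows())
    plan = load_substitution_plan()
    realization = realize_plan(groups, plan)

    rows = [
        {
            "group": r.group_label,
            "position": r.substitution.motif_position,
            "codon_before": r.edit.codon_before,
            "codon_after": r.edit.codon_after,
            "label": r.substitution.label,
            "edit_class": r.edit.edit_class,
        }
        for r in realization.realized
    ]
    table = pd.DataFrame(rows).sort_values(["position", "group"])
    table.to_csv(OUT / "substitutions.tsv", sep="\t", index=False)

    classes = sorted(c.label for c in distinct_classes(realization.realized))
    print(f"{len(realization.realized)} realized edits over {len(groups)} groups")
    print(f"{len(classes)} distinct substitution classes: {', '.join(classes)}")
    if realization.unmatched:
        print("unmatched plan entries:", realization.unmatched)
    print(f"wrote {OUT / 'substitutions.tsv'}")


if __name__ == "__main__":
    main()
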