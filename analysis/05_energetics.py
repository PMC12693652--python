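"""Classify binding-energy changes and summarize the cohort.

Recomputes DDG for the literature-reported mutations from the tabulated
wild-type/mutant interaction energies (explicit WT pairing), classifies
the 70-record evaluated grid against the method-specific cutoffs, and
writes results/ddg_classified.tsv plus results/cohort.json.
"""

import json
from pathlib import Path

import pandas as pd

from cambd.energetics import (
    classify_ddg,
    ddg_from_dg,
    load_wt_map,
    parse_foldx_output,
    summarize_cohort,
)
from cambd.reference import load_ddg_table, load_foldx_dg_text, load_wt_map_path

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = parse_foldx_output(load_foldx_dg_text())
    with load_wt_map_path() as p:
        wt_map = load_wt_map(p)
    lit = ddg_from_dg(records, wt_map)
    print("literature-mutation DDG recomputed from interaction energies:")
    table3 = load_ddg_table()
    printed_lit = table3[(table3["set"] == "literature") & (table3["method"] == "foldx")]
    printed = dict(zip(printed_lit["substitution"], printed_lit["ddg"]))
    for _, row in lit.iterrows():
        mut = row["complex_id"].split("_")[1]
        flag = ""
        if mut in printed and abs(printed[mut] - row["ddg"]) > 1e-9:
            flag = f"  [tabulated value {printed[mut]} is inconsistent; keeping the arithmetic]"
        print(f"  {row['complex_id']:<24} {row['ddg']:+.2f} kcal/mol{flag}")

    ev = table3[table3["set"] == "evaluated"]
    classifications = [
        classify_ddg(r.ddg, r.method, complex_id=r.complex_id, substitution=r.substitution)
        for r in ev.itertuples()
    ]
    classified = pd.DataFrame(
        {
            "complex_id": [c.complex_id for c in classifications],
            "substitution": [c.substitution for c in classifications],
            "method": [c.method for c in classifications],
            "ddg": [c.ddg for c in classifications],
            "cutoff": [c.cutoff for c in classifications],
            "label": [c.label for c in classifications],
        }
    )
    classified.to_csv(OUT / "ddg_classified.tsv", sep="\t", index=False)

    summary = summarize_cohort(classifications)
    payload = {
        "n_total": summary.n_total,
        "n_within": summary.n_within,
        "n_weakening": summary.n_weakening,
        "n_strengthening": summary.n_strengthening,
        "by_method": summary.by_method,
    }
    (OUT / "cohort.json").write_text(json.dumps(payload, indent=2) + "\n")

    fx = classified[classified["method"] == "foldx"]
    top = fx.loc[fx["ddg"].idxmax()]
    print(
        f"cohort: n={summary.n_total}, within error {summary.n_within}, "
        f"weakening {summary.n_weakening}, strengthening {summary.n_strengthening}"
    )
    print(f"largest destabilization: {top['complex_id']} {top['substitution']} "
          f"{top['ddg']:+.2f} kcal/mol")
    print(f"wrote {OUT / 'ddg_classified.tsv'} and cohort.json")


if __name__ == "__main__":
    main()
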