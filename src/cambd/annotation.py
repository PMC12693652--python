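"""Predictor-score categories and gene-disease association context.

Ingested functional-impact scores (0 benign .. 1 damaging) are binned
into the usual three categories; gene-disease association (GDA) exports
are filtered by confidence score and association type, and diseases are
stratified by polygenicity (how many genes the disease is linked to).
All inputs are user-supplied CSV exports — no live database queries.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CATEGORIES",
    "categorize_score",
    "filter_gda",
    "polygenicity_class",
    "expression_matrix",
]

#: category order from least to most damaging
CATEGORIES = ("benign", "possibly_damaging", "probably_damaging")

# Score bins: <0.2 benign, [0.2, 0.85) possibly damaging, >=0.85 probably
# damaging (half-open so the 0.85 boundary is probably damaging).
_BENIGN_MAX = 0.2
_PROBABLY_MIN = 0.85


def categorize_score(score: float) -> str:
    """Bin a 0-1 damage score into benign / possibly / probably damaging."""
    if not 0 <= score <= 1:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < _BENIGN_MAX:
        return "benign"
    if score < _PROBABLY_MIN:
        return "possibly_damaging"
    return "probably_damaging"


def filter_gda(
    records: pd.DataFrame, min_score: float = 0.3, types: set[str] | None = None
) -> pd.DataFrame:
    """Keep associations with score_gda >= min_score and a retained type.

    ``types`` defaults to {"CausalMutation", "GeneticVariation"}, the
    variant-level association classes; row order is preserved.
    """
    if types is None:
        types = {"CausalMutation", "GeneticVariation"}
    mask = (records["score_gda"] >= min_score) & records["association_type"].isin(types)
    return records.loc[mask]


def polygenicity_class(n_genes_disease: int) -> tuple[str, str]:
    """(monogenic/oligogenic/polygenic, low/high stratum) for a disease.

    One linked gene is monogenic, two oligogenic, three or more polygenic;
    the stratum splits at <=30 vs >30 linked genes (an operational
    prioritization boundary, not a biological constant).
    """
    n = int(n_genes_disease)
    if n < 1:
        raise ValueError("a disease must be linked to at least one gene")
    if n == 1:
        cls = "monogenic"
    elif n == 2:
        cls = "oligogenic"
    else:
        cls = "polygenic"
    return cls, ("low" if n <= 30 else "high")


def expression_matrix(flags: pd.DataFrame) -> pd.DataFrame:
    """Gene x tissue presence/absence matrix from high-expression flags.

    ``flags`` has columns gene, tissue_or_cell, high.  Duplicate identical
    flags are collapsed; contradictory duplicates (same gene/tissue with
    both True and False) are an error.  Columns are sorted
    lexicographically for determinism.
    """
    if flags.empty:
        return pd.DataFrame()
    dedup = flags.drop_duplicates()
    key_counts = dedup.groupby(["gene", "tissue_or_cell"]).size()
    if (key_counts > 1).any():
        clash = key_counts[key_counts > 1].index.tolist()
        raise ValueError(f"contradictory expression flags for {clash}")
    mat = (
        dedup.assign(high=dedup["high"].astype(int))
        .pivot(index="gene", columns="tissue_or_cell", values="high")
        .fillna(0)
        .astype(int)
    )
    return mat.sort_index(axis=0).sort_index(axis=1)
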