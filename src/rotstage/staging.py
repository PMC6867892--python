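"""Temporal trend classification: eight subgroups, pooled early/late sets.

Each gene's DEG directions across the three section contrasts form a triple
(d_BA, d_CA, d_CB) with A = 0-5 mm (hyphal front), B = 15-20 mm,
C = 30-35 mm, and '+' meaning significantly higher in the later section of
the contrast.  Trend-consistent triples map onto eight subgroups: I-IV peak
at the hyphal front ("early", expression decreasing with decay), V-VIII
peak in older sections ("late", expression increasing with decay).  Any
other triple - including contradictory ones - is left unstaged.
"""

from __future__ import annotations

import pandas as pd

from rotstage.express import CONTRASTS, contrast_name

#: contrast names in triple order (d_BA, d_CA, d_CB)
TRIPLE_ORDER = tuple(contrast_name(e, l) for e, l in CONTRASTS)

TRIPLE_TO_SUBGROUP: dict[tuple[str, str, str], str] = {
    ("-", "-", "-"): "I",
    ("-", "-", "0"): "II",
    ("-", "0", "+"): "III",
    ("0", "-", "-"): "IV",
    ("+", "+", "+"): "V",
    ("+", "+", "0"): "VI",
    ("+", "0", "-"): "VII",
    ("0", "+", "+"): "VIII",
}

EARLY_SUBGROUPS = frozenset({"I", "II", "III", "IV"})
LATE_SUBGROUPS = frozenset({"V", "VI", "VII", "VIII"})


def classify_triple(triple: tuple[str, str, str]) -> tuple[str, str]:
    """Map one direction triple to (subgroup, stage)."""
    subgroup = TRIPLE_TO_SUBGROUP.get(tuple(triple), "none")
    if subgroup in EARLY_SUBGROUPS:
        return subgroup, "early"
    if subgroup in LATE_SUBGROUPS:
        return subgroup, "late"
    return "none", "none"


def classify_trends(de: pd.DataFrame) -> pd.DataFrame:
    """Assign a subgroup and decay stage to every gene of a DE table.

    ``de`` must carry gene_id, contrast and direction columns covering all
    three section contrasts (the output of :func:`rotstage.express.run_de`).
    """
    directions = de.pivot(index="gene_id", columns="contrast", values="direction")
    missing = [c for c in TRIPLE_ORDER if c not in directions.columns]
    if missing:
        raise ValueError(f"missing contrast(s): {missing}")
    if directions[list(TRIPLE_ORDER)].isna().any().any():
        raise ValueError("direction table has gaps; every gene needs all three contrasts")
    assigned = [
        classify_triple(t)
        for t in directions[list(TRIPLE_ORDER)].itertuples(index=False, name=None)
    ]
    out = pd.DataFrame(assigned, index=directions.index, columns=["subgroup", "stage"])
    return out.reset_index()


def pool_stage_sets(assignments: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Pool subgroups I-IV into the early-upregulated DEG set and V-VIII
    into the late set.  The two sets are disjoint by construction."""
    early = set(assignments.loc[assignments["stage"] == "early", "gene_id"])
    late = set(assignments.loc[assignments["stage"] == "late", "gene_id"])
    return early, late
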