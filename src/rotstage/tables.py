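"""Published reference table of brown-rot-unique decay-stage-dependent DEGs.

The packaged TSV transcribes the curated catalog of ortholog groups found
to be uniquely early- or late-upregulated in the two brown-rot fungi
(*G. trabeum* and *P. placenta*): one row per ortholog group with its
functional description, stage, and the RPKM / fold-change values printed
for each species.  Nineteen ortholog groups encoding ribosomal-structure
proteins were published as a single combined row; ``n_groups`` carries
that multiplicity so totals can be expanded.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "data/brown_rot_unique_degs.tsv"


def load_brown_rot_unique_degs() -> pd.DataFrame:
    """Load the printed brown-rot-unique DEG table (one row per entry)."""
    with resources.files("rotstage").joinpath(_DATA).open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    if (df["n_groups"] < 1).any():
        raise ValueError("entry multiplicities must be >= 1")
    return df


def brown_rot_unique_counts(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Stage-wise and total counts of brown-rot-unique DEGs, expanding the
    combined ribosomal entry into its 19 member groups."""
    if table is None:
        table = load_brown_rot_unique_degs()
    by_stage = table.groupby("stage")["n_groups"].sum()
    early = int(by_stage.get("early", 0))
    late = int(by_stage.get("late", 0))
    return {"early": early, "late": late, "total": early + late}
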