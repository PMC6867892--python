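"""Classify each gene's temporal trend into the eight subgroups and pool
decay-stage-dependent DEGs into early (hyphal front) and late sets.

Writes stages_<sp>.tsv (gene_id, subgroup, stage).
"""

import argparse
from pathlib import Path

import pandas as pd

from rotstage.staging import classify_trends, pool_stage_sets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--outdir", type=Path, default=Path("results/stages"))
    args = ap.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    for de_path in sorted(args.dedir.glob("de_*.tsv")):
        sp = de_path.stem.removeprefix("de_")
        de = pd.read_csv(de_path, sep="\t")
        assigned = classify_trends(de)
        assigned.insert(1, "species", sp)
        assigned.to_csv(args.outdir / f"stages_{sp}.tsv", sep="\t", index=False)
        early, late = pool_stage_sets(assigned)
        by_subgroup = assigned[assigned["subgroup"] != "none"]["subgroup"].value_counts()
        print(f"{sp}: {len(early)} early / {len(late)} late decay-stage-dependent "
              f"DEGs; subgroups: {by_subgroup.sort_index().to_dict()}")


if __name__ == "__main__":
    main()
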