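"""Cross-species comparison through ortholog groups: Venn partition of the
early/late DEG sets (brown-unique, white-unique, common cells), early-to-
late ratio profiles, Spearman correlation of samples and complete-linkage
clustering.

Writes venn_<stage>.tsv, ratio_profile.tsv, correlation.tsv, dendrogram.nwk.
"""

import argparse
from pathlib import Path

import pandas as pd

from rotstage.crossspecies import (
    assign_orthodeg_ids,
    correlation_matrix,
    hierarchical_cluster,
    linkage_to_newick,
    replicate_ratio_profile,
    venn_partition,
)
from rotstage.staging import pool_stage_sets
from rotstage.synthdata import read_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--stagedir", type=Path, default=Path("results/stages"))
    ap.add_argument("--outdir", type=Path, default=Path("results/crossspecies"))
    args = ap.parse_args()

    ds = read_dataset(args.datadir)
    rot_type = dict(zip(ds.design["species"], ds.design["rot_type"]))
    args.outdir.mkdir(parents=True, exist_ok=True)

    early_sets, late_sets, rpkm = {}, {}, {}
    for path in sorted(args.stagedir.glob("stages_*.tsv")):
        sp = path.stem.removeprefix("stages_")
        early_sets[sp], late_sets[sp] = pool_stage_sets(pd.read_csv(path, sep="\t"))
        rpkm[sp] = pd.read_csv(args.dedir / f"rpkm_{sp}.tsv", sep="\t", index_col=0)

    ortho_early = assign_orthodeg_ids(early_sets, ds.orthologs, ds.annotation)
    ortho_late = assign_orthodeg_ids(late_sets, ds.orthologs, ds.annotation)
    for stage, sets in (("early", ortho_early), ("late", ortho_late)):
        venn = venn_partition(sets, rot_type, stage=stage)
        venn.to_frame().to_csv(args.outdir / f"venn_{stage}.tsv", sep="\t", index=False)
        print(f"{stage}: {len(venn.brown_unique)} brown-rot-unique, "
              f"{len(venn.white_unique)} white-rot-unique, "
              f"{len(venn.common_to_all)} common-to-all ortho-DEGs")

    profile = replicate_ratio_profile(rpkm, ds.design, ds.orthologs)
    deg_groups = sorted(
        set().union(*ortho_early.values(), *ortho_late.values()) & set(profile.index)
    )
    profile.loc[deg_groups].to_csv(args.outdir / "ratio_profile.tsv", sep="\t")
    corr = correlation_matrix(profile.loc[deg_groups])
    corr.to_csv(args.outdir / "correlation.tsv", sep="\t")
    z, labels = hierarchical_cluster(corr.fillna(0.0))
    (args.outdir / "dendrogram.nwk").write_text(linkage_to_newick(z, labels) + "\n")
    print(f"{len(deg_groups)} ortho-DEG groups used for sample correlation/clustering")


if __name__ == "__main__":
    main()
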