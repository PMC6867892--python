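"""Functional-investment statistics: LOX/GH DEG counts per family, the
rot-type LOX early-shift tests (Fisher + paired t), term enrichment of the
brown-rot early set, GH:LOX transcription ratios and family-expression PCA.

Writes family_counts.tsv, shift_tests.tsv, enrichment_brown_early.tsv,
investment.tsv, pca_scores.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from rotstage.express import section_mean_rpkm
from rotstage.investment import (
    family_deg_counts,
    family_expression_matrix,
    fisher_enrichment,
    investment_ratio,
    lox_shift_tests,
    pca,
)
from rotstage.staging import pool_stage_sets
from rotstage.synthdata import SECTIONS, read_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--stagedir", type=Path, default=Path("results/stages"))
    ap.add_argument("--outdir", type=Path, default=Path("results/investment"))
    args = ap.parse_args()

    ds = read_dataset(args.datadir)
    rot_type = dict(zip(ds.design["species"], ds.design["rot_type"]))
    args.outdir.mkdir(parents=True, exist_ok=True)

    early_sets, late_sets, section_means = {}, {}, {}
    for path in sorted(args.stagedir.glob("stages_*.tsv")):
        sp = path.stem.removeprefix("stages_")
        early_sets[sp], late_sets[sp] = pool_stage_sets(pd.read_csv(path, sep="\t"))
        rpkm = pd.read_csv(args.dedir / f"rpkm_{sp}.tsv", sep="\t", index_col=0)
        section_means[sp] = section_mean_rpkm(rpkm, ds.design)

    fam = family_deg_counts(early_sets, late_sets, ds.annotation)
    fam.to_csv(args.outdir / "family_counts.tsv", sep="\t", index=False)
    shift = lox_shift_tests(fam, rot_type)
    rows = [{"test": "fisher_lox_rot_x_stage", "statistic": shift.fisher_odds,
             "pvalue": shift.fisher_p, "degenerate": shift.degenerate}]
    rows += [{"test": f"paired_t_{cls}", "statistic": t, "pvalue": p, "degenerate": False}
             for cls, (t, p) in shift.paired_t.items()]
    pd.DataFrame(rows).to_csv(args.outdir / "shift_tests.tsv", sep="\t", index=False)
    (be, bl), (we, wl) = shift.fisher_table
    print(f"pooled LOX DEGs  brown {be} early/{bl} late, white {we} early/{wl} late; "
          f"Fisher p = {shift.fisher_p:.2g}")

    # enrichment of the brown-rot-pooled early set against flat GO-style terms
    brown = [sp for sp, r in rot_type.items() if r == "brown"]
    target = set().union(*(early_sets[sp] for sp in brown))
    universe = set(ds.annotation.index[ds.annotation["species"].isin(brown)])
    terms: dict[str, set] = {}
    for gene, term_str in ds.annotation.loc[sorted(universe), "go_terms"].items():
        for term in str(term_str).split(";"):
            if term:
                terms.setdefault(term, set()).add(gene)
    enrich = fisher_enrichment(target & universe, universe, terms)
    enrich.to_csv(args.outdir / "enrichment_brown_early.tsv", sep="\t", index=False)
    top = enrich.sort_values("pvalue").head(1)
    if len(top):
        print(f"top enriched term in brown-rot early DEGs: "
              f"{top.iloc[0]['term']} (FDR {top.iloc[0]['fdr']:.2g})")

    inv = investment_ratio(section_means, ds.annotation)
    inv.to_csv(args.outdir / "investment.tsv", sep="\t", index=False)
    late = inv[inv["section"] == SECTIONS[2]].set_index("species")["gh_lox_ratio"]
    print("late-section GH:LOX ratios:", late.round(2).to_dict())

    mat = family_expression_matrix(section_means, ds.annotation)
    scores, _, explained = pca(mat)
    pd.DataFrame(
        scores[:, :2], index=mat.index, columns=["PC1", "PC2"]
    ).to_csv(args.outdir / "pca_scores.tsv", sep="\t")
    print(f"family-expression PCA: PC1 {explained[0]:.1%}, PC2 {explained[1]:.1%} "
          "of variance")


if __name__ == "__main__":
    main()
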