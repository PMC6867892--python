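"""Simulate the wafer-decay experiment: 2 brown-rot + 2 white-rot species,
3 wafer sections x 3 bioreplicates of NB gene counts with injected
LOX-early / GH-late programs, plus annotations, ortholog groups and truth.

Writes samples.tsv, annotation.tsv, orthologs.tsv, truth.tsv and one
counts_<species>.tsv per species.
"""

import argparse
from pathlib import Path

from rotstage.synthdata import SimulationConfig, simulate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/simulated"))
    ap.add_argument("--n-orthogroups", type=int, default=None)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    if args.n_orthogroups:
        cfg = SimulationConfig(seed=args.seed, n_orthogroups=args.n_orthogroups)
    ds = simulate_dataset(cfg)
    write_dataset(ds, args.outdir)

    staged = ds.truth.groupby(["species", "stage"]).size().unstack(fill_value=0)
    print(f"simulated {len(ds.design)} samples, {len(ds.annotation)} genes, "
          f"{ds.orthologs['group_id'].nunique()} ortholog groups -> {args.outdir}")
    print("injected stage programs per species:")
    print(staged.to_string())


if __name__ == "__main__":
    main()
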