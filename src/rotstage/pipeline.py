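"""End-to-end pipeline over a (synthetic or loaded) decay-gradient dataset.

Runs every stage in order: RPKM normalisation, per-species DE testing and
dispersion estimation, temporal trend classification, ortholog-group Venn
partition of the early/late DEG sets, correlation + clustering of the
species' temporal profiles, and the functional-investment statistics.  The
result bundle keeps each intermediate table so drivers and tests can
inspect or write any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from rotstage import crossspecies, express, investment, staging
from rotstage.express import DispersionEstimate
from rotstage.synthdata import SimulationConfig, SyntheticDataset, simulate_dataset


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    rpkm: dict[str, pd.DataFrame]
    section_means: dict[str, pd.DataFrame]
    evidence: dict[str, pd.Series]
    dispersions: dict[str, DispersionEstimate]
    de_tables: dict[str, pd.DataFrame]
    stage_tables: dict[str, pd.DataFrame]
    early_sets: dict[str, set[str]]
    late_sets: dict[str, set[str]]
    ortho_early: dict[str, set[str]]
    ortho_late: dict[str, set[str]]
    venn_early: crossspecies.VennPartition
    venn_late: crossspecies.VennPartition
    ratio_profile: pd.DataFrame
    correlation: pd.DataFrame
    linkage: object
    linkage_labels: list[str]
    family_counts: pd.DataFrame
    shift_tests: investment.ShiftTestResult
    investment_summary: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(
    dataset: SyntheticDataset | None = None,
    config: SimulationConfig | None = None,
    phi: float | None = None,
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.05,
) -> PipelineResult:
    """Execute the complete analysis.

    Either pass a ready ``dataset`` or a ``config`` to simulate one.  If
    ``phi`` is given it is used for every species' exact tests; otherwise a
    common dispersion is estimated per species.
    """
    if dataset is None:
        dataset = simulate_dataset(config or SimulationConfig())
    design = dataset.design
    annotation = dataset.annotation
    rot_type = dict(zip(design["species"], design["rot_type"]))

    rpkm: dict[str, pd.DataFrame] = {}
    section_means: dict[str, pd.DataFrame] = {}
    evidence: dict[str, pd.Series] = {}
    dispersions: dict[str, DispersionEstimate] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    stage_tables: dict[str, pd.DataFrame] = {}
    early_sets: dict[str, set[str]] = {}
    late_sets: dict[str, set[str]] = {}

    for sp, counts in dataset.counts.items():
        lengths = annotation.loc[counts.index, "length_bp"]
        rpkm[sp] = express.compute_rpkm(counts, lengths)
        section_means[sp] = express.section_mean_rpkm(rpkm[sp], design)
        evidence[sp] = express.expression_evidence(section_means[sp])
        de, est = express.run_de(
            counts, design, phi=phi, fc_threshold=fc_threshold, fdr_threshold=fdr_threshold
        )
        if est is not None:
            dispersions[sp] = est
        de_tables[sp] = de
        stage_tables[sp] = staging.classify_trends(de)
        early_sets[sp], late_sets[sp] = staging.pool_stage_sets(stage_tables[sp])

    ortho_early = crossspecies.assign_orthodeg_ids(early_sets, dataset.orthologs, annotation)
    ortho_late = crossspecies.assign_orthodeg_ids(late_sets, dataset.orthologs, annotation)
    venn_early = crossspecies.venn_partition(ortho_early, rot_type, stage="early")
    venn_late = crossspecies.venn_partition(ortho_late, rot_type, stage="late")

    # correlate species' temporal programs over ortho-DEG groups only
    profile = crossspecies.replicate_ratio_profile(rpkm, design, dataset.orthologs)
    deg_groups = sorted(
        set().union(*ortho_early.values(), *ortho_late.values()) & set(profile.index)
    )
    restricted = profile.loc[deg_groups] if deg_groups else profile
    correlation = crossspecies.correlation_matrix(restricted, method="spearman")
    z, labels = crossspecies.hierarchical_cluster(correlation.fillna(0.0))

    fam_counts = investment.family_deg_counts(early_sets, late_sets, annotation)
    shift = investment.lox_shift_tests(fam_counts, rot_type)
    invest = investment.investment_ratio(section_means, annotation)

    return PipelineResult(
        dataset=dataset,
        rpkm=rpkm,
        section_means=section_means,
        evidence=evidence,
        dispersions=dispersions,
        de_tables=de_tables,
        stage_tables=stage_tables,
        early_sets=early_sets,
        late_sets=late_sets,
        ortho_early=ortho_early,
        ortho_late=ortho_late,
        venn_early=venn_early,
        venn_late=venn_late,
        ratio_profile=profile,
        correlation=correlation,
        linkage=z,
        linkage_labels=labels,
        family_counts=fam_counts,
        shift_tests=shift,
        investment_summary=invest,
    )


def truth_stage_sets(dataset: SyntheticDataset, species: str) -> tuple[set[str], set[str]]:
    """Ground-truth early/late gene sets for one species."""
    t = dataset.truth[dataset.truth["species"] == species]
    return (
        set(t.index[t["stage"] == "early"]),
        set(t.index[t["stage"] == "late"]),
    )


def truth_rotunique_groups(dataset: SyntheticDataset, stage: str, rot: str = "brown") -> set[str]:
    """Ortholog groups whose intended stage is ``stage`` in every species of
    rot type ``rot`` (with >= 1 member there) and in no species of the
    other type — the ground truth for the rot-unique Venn cell."""
    truth = dataset.truth
    rot_of = dataset.config.rot_type
    wanted = {s for s, r in rot_of.items() if r == rot}
    out = set()
    for group_id, grp in truth.groupby("group_id"):
        staged = {
            sp: set(sub["stage"]) for sp, sub in grp.groupby("species")
        }
        in_rot = [sp for sp in staged if sp in wanted]
        out_rot = [sp for sp in staged if sp not in wanted]
        if len(in_rot) == len(wanted) and all(stage in staged[sp] for sp in in_rot):
            if not any(stage in staged[sp] for sp in out_rot):
                out.add(group_id)
    return out


def cluster_matches_rot_type(result: PipelineResult) -> bool:
    """True when cutting the sample dendrogram into two clusters separates
    brown-rot from white-rot samples perfectly."""
    split = crossspecies.cut_two_clusters(result.linkage, result.linkage_labels)
    rot_of = result.dataset.config.rot_type
    by_cluster: dict[int, set[str]] = {}
    for label, cl in split.items():
        sp = label.rsplit("_", 1)[0]
        by_cluster.setdefault(cl, set()).add(rot_of[sp])
    return all(len(types) == 1 for types in by_cluster.values()) and len(by_cluster) == 2
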