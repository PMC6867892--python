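"""Cross-species comparison of stage-dependent DEGs via ortholog groups.

Ortholog groups are either supplied (e.g. from OrthoMCL output) or built
with a reciprocal-best-hit surrogate: mutual best hits between species form
edges and connected components become groups.  Stage DEG sets are lifted to
group ids, partitioned into a four-species Venn diagram (brown-rot-unique,
white-rot-unique, common-to-all, and all other cells), and species are
clustered by the per-group early-to-late expression ratio
r = log2[RPKM(0-5mm) / mean(RPKM(15-20mm), RPKM(30-35mm))].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from rotstage.synthdata import SECTIONS, EARLY_SECTION, LATE_SECTIONS

RATIO_PSEUDOCOUNT = 0.1  # RPKM; far below the >5 expression-evidence cut


def build_orthogroups_rbh(similarity: pd.DataFrame) -> pd.DataFrame:
    """Cluster genes into ortholog groups by reciprocal best hits.

    ``similarity`` columns: species_a, gene_a, species_b, gene_b, score.
    For every (gene, other species) the best-scoring hit is found; a pair
    that is mutually best becomes an edge and connected components become
    groups (single linkage).  Group ids MCL_1, MCL_2, ... are assigned in
    sorted order of each component's smallest gene id, so output is
    deterministic.  Genes sharing an id across species are rejected.
    """
    fwd = similarity.rename(
        columns={"species_a": "qs", "gene_a": "qg", "species_b": "ts", "gene_b": "tg"}
    )
    rev = similarity.rename(
        columns={"species_b": "qs", "gene_b": "qg", "species_a": "ts", "gene_a": "tg"}
    )
    hits = pd.concat([fwd, rev], ignore_index=True)[["qs", "qg", "ts", "tg", "score"]]

    gene_species = pd.concat(
        [hits[["qg", "qs"]].rename(columns={"qg": "g", "qs": "s"}),
         hits[["tg", "ts"]].rename(columns={"tg": "g", "ts": "s"})],
        ignore_index=True,
    ).drop_duplicates()
    dup = gene_species.groupby("g")["s"].nunique()
    if (dup > 1).any():
        raise ValueError(f"gene ids duplicated across species: {list(dup[dup > 1].index[:3])}")

    # best hit per (query gene, target species); ties broken by gene id
    hits = hits.sort_values(["qg", "ts", "score", "tg"], ascending=[True, True, False, True])
    best = hits.drop_duplicates(["qg", "ts"], keep="first")
    best_map = {(q, t): g for q, t, g in zip(best["qg"], best["ts"], best["tg"])}

    graph = nx.Graph()
    species_of = dict(zip(gene_species["g"], gene_species["s"]))
    graph.add_nodes_from(species_of)
    for (qg, ts), tg in best_map.items():
        if best_map.get((tg, species_of[qg])) == qg and qg < tg:
            graph.add_edge(qg, tg)

    components = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    components.sort(key=lambda c: c[0])
    rows = [
        {"group_id": f"MCL_{i + 1}", "species": species_of[g], "gene_id": g}
        for i, comp in enumerate(components)
        for g in comp
    ]
    return pd.DataFrame(rows, columns=["group_id", "species", "gene_id"])


def gene_to_group(orthologs: pd.DataFrame) -> dict[str, str]:
    mapping = dict(zip(orthologs["gene_id"], orthologs["group_id"]))
    if len(mapping) != len(orthologs):
        raise ValueError("a gene may belong to at most one ortholog group")
    return mapping


def assign_orthodeg_ids(
    stage_sets: dict[str, set[str]],
    orthologs: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> dict[str, set[str]]:
    """Lift per-species gene-level DEG sets to ortholog-group ids.

    A group is a stage DEG for a species when any member gene of that
    species is in the set.  Genes without a group keep a species-specific
    id ``species|gene``.  If ``annotation`` is given, genes absent from it
    are rejected.
    """
    mapping = gene_to_group(orthologs)
    out: dict[str, set[str]] = {}
    for sp, genes in stage_sets.items():
        ids = set()
        for g in genes:
            if annotation is not None and g not in annotation.index:
                raise ValueError(f"gene {g} missing from annotation")
            ids.add(mapping.get(g, f"{sp}-specific|{g}"))
        out[sp] = ids
    return out


@dataclass
class VennPartition:
    """Partition of the union of four species' id sets into the 15
    species-combination cells."""

    stage: str
    cells: dict[frozenset, set[str]]
    rot_type: dict[str, str]

    def cell(self, *species: str) -> set[str]:
        return self.cells.get(frozenset(species), set())

    def _by_type(self, rot: str) -> list[str]:
        return sorted(s for s, t in self.rot_type.items() if t == rot)

    @property
    def brown_unique(self) -> set[str]:
        """Ids present in every brown-rot species and no white-rot species."""
        return self.cell(*self._by_type("brown"))

    @property
    def white_unique(self) -> set[str]:
        return self.cell(*self._by_type("white"))

    @property
    def common_to_all(self) -> set[str]:
        return self.cell(*self.rot_type.keys())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell": "+".join(sorted(combo)), "id": i}
            for combo, ids in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
            for i in sorted(ids)
        ]
        return pd.DataFrame(rows, columns=["cell", "id"])


def venn_partition(
    id_sets: dict[str, set[str]],
    rot_type: dict[str, str],
    stage: str = "",
) -> VennPartition:
    """Partition id sets of the four species into Venn cells.

    Every id in the union lands in exactly one cell, keyed by the exact
    combination of species whose sets contain it.
    """
    unknown = [s for s in id_sets if s not in rot_type]
    if unknown:
        raise ValueError(f"species without a rot type: {unknown}")
    species = sorted(id_sets)
    cells: dict[frozenset, set[str]] = {}
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            inside = set.intersection(*(id_sets[s] for s in combo)) if combo else set()
            outside = set().union(*(id_sets[s] for s in species if s not in combo), set())
            cells[frozenset(combo)] = inside - outside
    return VennPartition(stage=stage, cells=cells, rot_type=dict(rot_type))


def early_late_ratio(
    section_rpkm: dict[str, pd.DataFrame],
    orthologs: pd.DataFrame,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-group, per-species early-to-late expression ratio.

    ``section_rpkm`` maps species to a genes x sections RPKM table.  Member
    RPKM is summed per group (groups can hold paralogs), then
    r = log2[(RPKM_early + eps) / (mean of the two later sections + eps)].
    Species without a member gene get NaN (absent, not zero).
    """
    cols = {}
    for sp, table in section_rpkm.items():
        members = orthologs[orthologs["species"] == sp]
        present = members[members["gene_id"].isin(table.index)]
        summed = (
            table.loc[present["gene_id"], list(SECTIONS)]
            .groupby(present.set_index("gene_id")["group_id"])
            .sum()
        )
        early = summed[EARLY_SECTION] + pseudocount
        late = summed[list(LATE_SECTIONS)].mean(axis=1) + pseudocount
        cols[sp] = np.log2(early / late)
    return pd.DataFrame(cols)


def replicate_ratio_profile(
    rpkm: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    orthologs: pd.DataFrame,
    pseudocount: float = RATIO_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Early-to-late ratios per (species, replicate) sample unit.

    Like :func:`early_late_ratio` but keeping bioreplicates separate, giving
    the groups x (species_replicate) profile used to correlate and cluster
    individual RNA-seq samples.
    """
    cols = {}
    for sp, table in rpkm.items():
        sub = design[design["species"] == sp]
        for rep, rep_rows in sub.groupby("replicate"):
            sec_cols = rep_rows.set_index("section").loc[list(SECTIONS), :].index
            by_section = pd.DataFrame(
                {
                    sec: table[rep_rows.index[rep_rows["section"] == sec][0]]
                    for sec in SECTIONS
                }
            )
            prof = early_late_ratio({sp: by_section}, orthologs, pseudocount)[sp]
            cols[f"{sp}_{rep}"] = prof
    return pd.DataFrame(cols)


def correlation_matrix(
    profile: pd.DataFrame,
    method: str = "spearman",
    min_periods: int = 3,
) -> pd.DataFrame:
    """Sample x sample correlation of ratio profiles.

    Rows with missing values are dropped pairwise; pairs sharing fewer than
    ``min_periods`` groups are flagged missing (NaN).  Spearman uses average
    ranks for ties.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method: {method}")
    corr = profile.corr(method=method, min_periods=min_periods)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the rows of ``matrix`` (e.g. a
    correlation matrix, each row a sample's correlation vector).

    Returns the merge list as a SciPy linkage matrix plus row labels.
    Merge heights are non-decreasing for complete linkage.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    dist = pdist(values, metric=metric)
    return linkage(dist, method=method), list(matrix.index)


def cut_two_clusters(z: np.ndarray, labels: list[str]) -> dict[str, int]:
    """Split the dendrogram at its root into the two major clusters."""
    from scipy.cluster.hierarchy import fcluster

    assignment = fcluster(z, t=2, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assignment)))


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialise a SciPy linkage matrix as a Newick tree with branch
    lengths derived from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = z[i - n]
        la = node(int(a))
        lb = node(int(b))
        return (
            f"({la}:{h - heights[int(a)]:.6g},{lb}:{h - heights[int(b)]:.6g})"
        )

    for k, (_, _, h, _) in enumerate(z):
        heights[n + k] = h
    return node(n + len(z) - 1) + ";"
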