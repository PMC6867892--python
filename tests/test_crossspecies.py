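"""Orthology surrogate, Venn partition, temporal ratios, correlation and
clustering — with brute-force oracles for the numeric pieces."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from rotstage.crossspecies import (
    assign_orthodeg_ids,
    build_orthogroups_rbh,
    correlation_matrix,
    cut_two_clusters,
    early_late_ratio,
    hierarchical_cluster,
    linkage_to_newick,
    venn_partition,
)
from rotstage.synthdata import SECTIONS, SimulationConfig, generate_gene_catalog, similarity_table


def _sim(rows):
    return pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b", "gene_b", "score"])


class TestRbh:
    def test_mutual_best_hits_form_a_group(self):
        sim = _sim([("sp1", "a", "sp2", "x", 90.0), ("sp1", "b", "sp2", "x", 40.0)])
        groups = build_orthogroups_rbh(sim)
        assert set(groups["gene_id"]) == {"a", "x"}
        assert groups["group_id"].nunique() == 1

    def test_reciprocity_required(self):
        # a's best in sp2 is x, but x's best in sp1 is b
        sim = _sim(
            [("sp1", "a", "sp2", "x", 50.0), ("sp1", "b", "sp2", "x", 80.0)]
        )
        groups = build_orthogroups_rbh(sim)
        assert "a" not in set(groups["gene_id"])
        assert set(groups["gene_id"]) >= {"b", "x"}

    def test_duplicate_gene_ids_across_species_rejected(self):
        sim = _sim([("sp1", "dup", "sp2", "dup", 90.0)])
        with pytest.raises(ValueError):
            build_orthogroups_rbh(sim)

    def test_recovers_true_groups_from_generated_similarity(self):
        """With complete groups (a true partner in every species) and a
        generous score margin, every true best hit beats every noise hit
        and the reciprocal-best-hit components equal the true groups."""
        cfg = SimulationConfig(
            n_orthogroups=60, seed=13, completeness=1.0, duplication_prob=0.0
        )
        _, orthologs, _ = generate_gene_catalog(cfg)
        sim = similarity_table(orthologs, cfg, margin=30.0, n_noise_pairs=300)
        rebuilt = build_orthogroups_rbh(sim)
        true_parts = {
            frozenset(g["gene_id"]) for _, g in orthologs.groupby("group_id") if len(g) > 1
        }
        rebuilt_parts = {frozenset(g["gene_id"]) for _, g in rebuilt.groupby("group_id")}
        recovered = len(true_parts & rebuilt_parts) / len(true_parts)
        assert recovered == 1.0

    def test_deterministic_group_ids(self):
        sim = _sim(
            [("sp1", "a", "sp2", "x", 90.0), ("sp1", "c", "sp2", "z", 80.0)]
        )
        g1 = build_orthogroups_rbh(sim)
        g2 = build_orthogroups_rbh(sim.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(g1, g2)


class TestOrthoIds:
    ORTHO = pd.DataFrame(
        {
            "group_id": ["MCL_7", "MCL_7", "MCL_7"],
            "species": ["sp1", "sp2", "sp2"],
            "gene_id": ["g1", "g2", "g2b"],
        }
    )

    def test_group_and_orphan_ids(self):
        sets = {"sp1": {"g1"}, "sp2": {"g2", "orphan"}}
        ids = assign_orthodeg_ids(sets, self.ORTHO)
        assert ids["sp1"] == {"MCL_7"}
        assert ids["sp2"] == {"MCL_7", "sp2-specific|orphan"}

    def test_any_member_rule_for_paralogs(self):
        # one of two sp2 paralogs suffices for the group to count
        ids = assign_orthodeg_ids({"sp2": {"g2b"}}, self.ORTHO)
        assert ids["sp2"] == {"MCL_7"}

    def test_missing_annotation_rejected(self):
        ann = pd.DataFrame({"species": ["sp1"]}, index=["g1"])
        with pytest.raises(ValueError, match="ghost"):
            assign_orthodeg_ids({"sp1": {"ghost"}}, self.ORTHO, annotation=ann)


ROT = {"A": "brown", "B": "brown", "C": "white", "D": "white"}


class TestVenn:
    def test_brown_unique_definition(self):
        sets = {"A": {"x", "y"}, "B": {"x"}, "C": set(), "D": set()}
        part = venn_partition(sets, ROT)
        assert part.brown_unique == {"x"}
        assert part.cell("A") == {"y"}

    def test_identical_sets_all_common(self):
        sets = {s: {"m1", "m2"} for s in ROT}
        part = venn_partition(sets, ROT)
        assert part.common_to_all == {"m1", "m2"}
        assert part.brown_unique == set()

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({"E": {"x"}}, ROT)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_cells_partition_the_union(self, data):
        universe = [f"id{i}" for i in range(12)]
        sets = {
            s: set(data.draw(st.lists(st.sampled_from(universe), max_size=8)))
            for s in ROT
        }
        part = venn_partition(sets, ROT)
        cells = list(part.cells.values())
        union = set().union(*sets.values())
        assert set().union(*cells) == union
        assert sum(len(c) for c in cells) == len(union)  # pairwise disjoint


class TestRatio:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=list(SECTIONS))

    def test_closed_forms(self):
        ortho = pd.DataFrame(
            {"group_id": ["M1", "M2", "M3"], "species": "sp", "gene_id": ["g1", "g2", "g3"]}
        )
        rpkm = self._table([(8, 2, 2), (2, 4, 4), (0, 0, 0)]).set_axis(["g1", "g2", "g3"])
        r = early_late_ratio({"sp": rpkm}, ortho, pseudocount=0.0 + 0.1)
        assert r.at["M1", "sp"] == pytest.approx(np.log2(8.1 / 2.1))
        assert r.at["M2", "sp"] == pytest.approx(np.log2(2.1 / 4.1))
        assert r.at["M3", "sp"] == pytest.approx(0.0)

    def test_paralog_rpkm_summed_and_absent_species_nan(self):
        ortho = pd.DataFrame(
            {
                "group_id": ["M1", "M1", "M1"],
                "species": ["sp1", "sp1", "sp2"],
                "gene_id": ["a", "b", "c"],
            }
        )
        rpkm1 = self._table([(3, 1, 1), (5, 1, 1)]).set_axis(["a", "b"])
        rpkm2 = self._table([(1, 1, 1)]).set_axis(["z"])  # member c not expressed/absent
        r = early_late_ratio({"sp1": rpkm1, "sp2": rpkm2}, ortho, pseudocount=0.0)
        assert r.at["M1", "sp1"] == pytest.approx(2.0)  # log2(8/2), paralogs summed
        assert np.isnan(r.at["M1", "sp2"])

    def test_antisymmetric_under_block_swap(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        ortho = pd.DataFrame({"group_id": [f"M{i}" for i in range(20)], "species": "sp", "gene_id": genes})
        vals = rng.uniform(0, 50, (20, 3))
        fwd = pd.DataFrame(vals, index=genes, columns=list(SECTIONS))
        # swap the early block with the late pair mean by mirroring columns
        swapped = fwd.copy()
        late_mean = fwd[list(SECTIONS[1:])].mean(axis=1)
        swapped[SECTIONS[0]] = late_mean
        swapped[SECTIONS[1]] = fwd[SECTIONS[0]]
        swapped[SECTIONS[2]] = fwd[SECTIONS[0]]
        r1 = early_late_ratio({"sp": fwd}, ortho)["sp"]
        r2 = early_late_ratio({"sp": swapped}, ortho)["sp"]
        assert np.allclose(r1, -r2, atol=1e-12)


class TestCorrelation:
    def test_monotone_profiles(self):
        prof = pd.DataFrame({"u": [1.0, 2, 3, 4], "v": [10.0, 20, 30, 40], "w": [4.0, 3, 2, 1]})
        corr = correlation_matrix(prof, method="spearman")
        assert corr.at["u", "v"] == pytest.approx(1.0)
        assert corr.at["u", "w"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_ties_match_rank_then_pearson_oracle(self, data):
        n = data.draw(st.integers(4, 12))
        x = np.array(data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n)), float)
        y = np.array(data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n)), float)
        prof = pd.DataFrame({"x": x, "y": y})
        got = correlation_matrix(prof, method="spearman").at["x", "y"]
        rx, ry = rankdata(x), rankdata(y)  # average ranks for ties
        if np.std(rx) == 0 or np.std(ry) == 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_too_few_shared_observations_flagged(self):
        prof = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, np.nan], "y": [np.nan, 1.0, 2.0, 3.0]}
        )
        corr = correlation_matrix(prof)
        assert np.isnan(corr.at["x", "y"])

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        prof = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        c1 = correlation_matrix(prof)
        c2 = correlation_matrix(np.exp(prof * 2.0))
        pd.testing.assert_frame_equal(c1, c2, atol=1e-12, rtol=0)


def complete_linkage_oracle(points):
    """Naive O(n^3) complete-linkage agglomeration on euclidean distances.

    Returns the merge heights and, for the last merge, the two member sets
    it joined (the two-cluster partition)."""
    from scipy.spatial.distance import cdist

    clusters = {i: [i] for i in range(len(points))}
    d = cdist(points, points)
    heights = []
    last_children = None
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0] - 1e-15:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        last_children = (frozenset(clusters[a]), frozenset(clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights, last_children


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("abc"))
        z, labels = hierarchical_cluster(mat)
        assert z[0, 2] == pytest.approx(0.0)
        assert {labels[int(z[0, 0])], labels[int(z[0, 1])]} == {"a", "b"}

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(8, 4)))
        z, _ = hierarchical_cluster(mat)
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(3, 6))
        pts = np.array(
            data.draw(
                st.lists(
                    st.tuples(st.integers(-20, 20), st.integers(-20, 20)),
                    min_size=n, max_size=n, unique=True,
                )
            ),
            float,
        )
        mat = pd.DataFrame(pts)
        z, _ = hierarchical_cluster(mat)
        heights, last_children = complete_linkage_oracle(pts)
        assert np.allclose(sorted(z[:, 2]), sorted(heights), atol=1e-8)
        # the two-cluster partition must agree when the top merge height is
        # unambiguous (ties can legitimately reorder merges)
        if len(heights) < 2 or heights[-1] - max(heights[:-1]) > 1e-9:
            from scipy.cluster.hierarchy import fcluster

            flat = fcluster(z, t=2, criterion="maxclust")
            groups = {}
            for i, c in enumerate(flat):
                groups.setdefault(c, set()).add(i)
            assert set(map(frozenset, groups.values())) == set(last_children)

    def test_row_permutation_invariant_partition(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(7, 3)), index=[f"r{i}" for i in range(7)])
        z1, l1 = hierarchical_cluster(mat)
        perm = rng.permutation(7)
        z2, l2 = hierarchical_cluster(mat.iloc[perm])
        c1 = cut_two_clusters(z1, l1)
        c2 = cut_two_clusters(z2, l2)
        part1 = {frozenset(k for k, v in c1.items() if v == i) for i in set(c1.values())}
        part2 = {frozenset(k for k, v in c2.items() if v == i) for i in set(c2.values())}
        assert part1 == part2

    def test_non_finite_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            hierarchical_cluster(mat)

    def test_newick_serialisation_parses(self):
        import dendropy

        mat = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.2, 5.1]], index=list("wxyz")
        )
        z, labels = hierarchical_cluster(mat)
        tree = dendropy.Tree.get(data=linkage_to_newick(z, labels), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("wxyz")


class TestRotTypeClade:
    def test_brown_species_form_one_clade(self, small_run):
        """Injected rot-type programs separate brown from white samples at
        the top split of the dendrogram."""
        split = cut_two_clusters(small_run.linkage, small_run.linkage_labels)
        rot = small_run.dataset.config.rot_type
        by_cluster = {}
        for label, c in split.items():
            by_cluster.setdefault(c, set()).add(rot[label.rsplit("_", 1)[0]])
        assert all(len(v) == 1 for v in by_cluster.values())
        assert len(by_cluster) == 2
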