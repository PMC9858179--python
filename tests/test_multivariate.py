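"""Correlation matrix, network groups, Ward clustering and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from introqtl.multivariate import (
    Dendrogram,
    cluster_traits,
    cna_groups,
    correlation_graph,
    group_cluster_concordance,
    pearson_matrix,
    trait_distance,
    two_way_order,
    ward_hca,
)

from conftest import adjusted_rand, ward_oracle


def corr_df(arr, labels=None):
    labels = labels or [f"t{i}" for i in range(len(arr))]
    return pd.DataFrame(np.asarray(arr, dtype=float), index=labels,
                        columns=labels)


def brute_components(corr, threshold):
    """Union-find over all pairs, independent of networkx."""
    labels = list(corr.columns)
    parent = {x: x for x in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    arr = corr.to_numpy()
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if abs(arr[i, j]) > threshold:
                parent[find(labels[j])] = find(a)
    comps = {}
    for x in labels:
        comps.setdefault(find(x), set()).add(x)
    return {frozenset(c) for c in comps.values()}


class TestPearson:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(10, 6)),
                            columns=[f"t{i}" for i in range(6)])
        corr = pearson_matrix(data)
        arr = data.to_numpy()
        for i in range(6):
            for j in range(6):
                x, y = arr[:, i], arr[:, j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert corr.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_perfect_anticorrelation_and_diagonal(self):
        x = np.arange(5.0)
        data = pd.DataFrame({"a": x, "b": -x})
        corr = pearson_matrix(data)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.loc["a", "a"] == 1.0

    def test_zero_variance_trait_gets_zero_correlations(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr = pearson_matrix(data)
        assert corr.loc["a", "b"] == 0.0
        assert corr.loc["b", "b"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestCNA:
    def test_identity_matrix_gives_singletons(self):
        groups = cna_groups(corr_df(np.eye(4)))
        assert all(g.size == 1 for g in groups)
        assert len(groups) == 4

    def test_chain_forms_one_group(self):
        arr = np.eye(4)
        for i in range(3):
            arr[i, i + 1] = arr[i + 1, i] = 0.8
        (g,) = [g for g in cna_groups(corr_df(arr)) if g.size > 1]
        assert g.size == 4

    def test_threshold_is_strict(self):
        arr = np.eye(2)
        arr[0, 1] = arr[1, 0] = 0.7
        graph = correlation_graph(corr_df(arr), threshold=0.7)
        assert graph.number_of_edges() == 0

    def test_matches_union_find_oracle_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(2, 30))
            raw = rng.uniform(-1, 1, size=(n, n))
            arr = (raw + raw.T) / 2
            np.fill_diagonal(arr, 1.0)
            c = corr_df(arr)
            got = {frozenset(g.members) for g in cna_groups(c, 0.7)}
            assert got == brute_components(c, 0.7)

    def test_groups_sorted_by_size_then_member(self):
        arr = np.eye(5)
        arr[0, 1] = arr[1, 0] = 0.9
        arr[2, 3] = arr[3, 2] = 0.9
        groups = cna_groups(corr_df(arr, list("edcba")))
        assert [g.size for g in groups] == [2, 2, 1]
        assert groups[0].members == ("b", "c")  # tie broken by smallest id


class TestTraitDistance:
    def test_variants(self):
        c = corr_df([[1.0, -1.0], [-1.0, 1.0]])
        assert trait_distance(c, "abs").iloc[0, 1] == 0.0
        assert trait_distance(c, "signed").iloc[0, 1] == 2.0
        with pytest.raises(ValueError):
            trait_distance(c, "nope")

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(-1, 1, (6, 6))
        arr = np.clip((raw + raw.T) / 2, -1, 1)
        np.fill_diagonal(arr, 1.0)
        d = trait_distance(corr_df(arr))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


def random_distance(rng, n):
    raw = rng.uniform(0.1, 2.0, (n, n))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=[f"x{i}" for i in range(n)],
                        columns=[f"x{i}" for i in range(n)])


class TestWard:
    def test_two_items_merge_at_their_distance(self):
        d = corr_df([[0.0, 0.7], [0.7, 0.0]], ["a", "b"])
        dend = ward_hca(d)
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(0.7)

    def test_duplicates_merge_first_at_zero(self):
        d = random_distance(np.random.default_rng(0), 4)
        d.iloc[0, 1] = d.iloc[1, 0] = 0.0
        dend = ward_hca(d)
        assert dend.merges[0].height == 0.0
        assert {dend.merges[0].left, dend.merges[0].right} == {0, 1}

    @pytest.mark.parametrize("variant,squared", [("classic", False),
                                                 ("squared", True)])
    def test_merge_sequence_matches_from_scratch_oracle(self, variant, squared):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(5, 9))
            d = random_distance(rng, n)
            dend = ward_hca(d, variant=variant)
            oracle = ward_oracle(d.to_numpy(), squared)
            for merge, (a, b, h) in zip(dend.merges, oracle):
                assert {merge.left, merge.right} == {a, b}
                assert merge.height == pytest.approx(h, rel=1e-9)

    def test_squared_variant_matches_scipy_heights(self):
        rng = np.random.default_rng(9)
        d = random_distance(rng, 7)
        dend = ward_hca(d, variant="squared")
        condensed = d.to_numpy()[np.triu_indices(7, 1)]
        sp = linkage(condensed, method="ward")
        assert np.allclose(sorted(m.height for m in dend.merges),
                           sorted(sp[:, 2]), rtol=1e-9)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            dend = ward_hca(random_distance(rng, 8))
            heights = [m.height for m in dend.merges]
            assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_asymmetric_input_rejected(self):
        d = corr_df([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            ward_hca(d)


class TestCutK:
    def make_blocks(self, rng, sizes, within=0.9):
        n = sum(sizes)
        arr = np.zeros((n, n))
        start = 0
        truth = {}
        for bi, size in enumerate(sizes):
            for i in range(start, start + size):
                truth[f"t{i}"] = bi
                for j in range(start, start + size):
                    arr[i, j] = within
            start += size
        arr += rng.uniform(-0.05, 0.05, (n, n))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        return corr_df(np.clip(arr, -1, 1)), truth

    def test_extreme_cuts(self):
        d = random_distance(np.random.default_rng(3), 6)
        dend = ward_hca(d)
        assert set(dend.cut_k(1).values()) == {0}
        assert len(set(dend.cut_k(6).values())) == 6
        with pytest.raises(ValueError):
            dend.cut_k(0)
        with pytest.raises(ValueError):
            dend.cut_k(7)

    def test_three_block_panel_recovered_exactly(self):
        rng = np.random.default_rng(21)
        corr, truth = self.make_blocks(rng, [6, 5, 7])
        _, labels = cluster_traits(corr, k=3)
        assert adjusted_rand(truth, labels) == pytest.approx(1.0)


class TestTwoWay:
    def sample_panel(self, rng, n_samples=12, n_traits=8):
        data = rng.normal(size=(n_samples, n_traits))
        return pd.DataFrame(
            data, index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_traits)],
        )

    def test_row_permutation_leaves_memberships_invariant(self):
        rng = np.random.default_rng(30)
        data = self.sample_panel(rng)
        t1, _, _ = two_way_order(data)
        perm = data.sample(frac=1.0, random_state=1)
        t2, _, _ = two_way_order(perm)
        assert t1.cut_k(3) == t2.cut_k(3)

    def test_reordered_matrix_is_a_permutation(self):
        rng = np.random.default_rng(31)
        data = self.sample_panel(rng)
        _, _, reordered = two_way_order(data)
        assert sorted(reordered.index) == sorted(data.index)
        assert sorted(reordered.columns) == sorted(data.columns)
        assert np.allclose(
            reordered.loc[data.index, data.columns], data
        )

    def test_duplicate_samples_adjacent(self):
        rng = np.random.default_rng(32)
        data = self.sample_panel(rng, n_samples=6)
        data.loc["s1"] = data.loc["s0"]  # exact duplicate profile
        _, sample_dend, reordered = two_way_order(data)
        order = list(reordered.index)
        assert abs(order.index("s0") - order.index("s1")) == 1

    def test_single_sample_gives_trivial_column_tree(self):
        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["s0"],
                            columns=["a", "b", "c"])
        _, sample_dend, _ = two_way_order(data)
        assert sample_dend.n_leaves == 1


class TestConcordance:
    def groups_of(self, mapping):
        from introqtl.multivariate import VOCGroup

        inv = {}
        for item, g in mapping.items():
            inv.setdefault(g, []).append(item)
        return [VOCGroup(str(g), tuple(sorted(v))) for g, v in inv.items()]

    def test_identical_partitions_have_unit_jaccard(self):
        mapping = {"a": 0, "b": 0, "c": 1}
        table, jacc = group_cluster_concordance(
            self.groups_of(mapping), mapping
        )
        assert np.allclose(np.sort(jacc.max(axis=1)), [1.0, 1.0])

    def test_refinement_maps_each_group_into_one_cluster(self):
        groups = self.groups_of({"a": 0, "b": 0, "c": 1, "d": 2})
        clusters = {"a": 0, "b": 0, "c": 0, "d": 1}
        table, _ = group_cluster_concordance(groups, clusters)
        assert ((table > 0).sum(axis=1) == 1).all()

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        items = [f"i{k}" for k in range(30)]
        ga = {i: int(rng.integers(4)) for i in items}
        gb = {i: int(rng.integers(3)) for i in items}
        table, _ = group_cluster_concordance(self.groups_of(ga), gb)
        for g in table.index:
            for c in table.columns:
                manual = sum(
                    1 for i in items if str(ga[i]) == g and gb[i] == c
                )
                assert table.loc[g, c] == manual

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            group_cluster_concordance(
                self.groups_of({"a": 0}), {"a": 0, "b": 1}
            )


class TestNewick:
    def test_round_trip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(14)
        dend = ward_hca(random_distance(rng, 6))
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(dend.labels)

    def test_single_leaf(self):
        d = Dendrogram(labels=["only"], merges=[])
        assert d.to_newick().endswith(";")
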