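"""Expression-rate statistics, clustering, groups, consistency scoring."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from logicnet import (BooleanModel, ExpressionAnnotation, brute_force_fixed_points,
                      group_rate_table, kmeans_cluster, make_clustered_states,
                      merge_to_groups, model_consistency, nonconstant_nodes,
                      rate_of_one, solve, standardize, states_matrix)
from logicnet.expr import And, Var
from logicnet.fixedpoints import Cube, CubeSet

from conftest import random_rule_model


class TestRates:
    def test_single_cube_rates(self):
        cs = CubeSet(["A", "B"], [Cube.make({"A": 1}, {"B"})])
        rates = rate_of_one(cs)
        assert rates == {"A": 1.0, "B": 0.5}

    def test_mutual_activation_rates(self, mutual_activation):
        rates = rate_of_one(solve(mutual_activation))
        assert rates == {"A": 0.5, "B": 0.5}

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            rate_of_one(CubeSet(["A"], []))

    def test_cube_rates_equal_expansion_rates(self):
        """Cube-analytic rates agree exactly with rates recomputed from
        the full expansion, for every random model small enough."""
        for seed in range(30):
            m = random_rule_model(seed, n_max=10)
            fps = solve(m)
            if fps.cardinality == 0 or fps.cardinality > 1 << 14:
                continue
            states = np.array(
                [[s[n] for n in fps.nodes] for s in fps.expand()])
            exact = rate_of_one(fps)
            for j, n in enumerate(fps.nodes):
                assert exact[n] == pytest.approx(states[:, j].mean(), abs=0)

    def test_nonconstant_nodes(self):
        cs = CubeSet(["A", "B", "C"],
                     [Cube.make({"A": 1, "B": 0}, {"C"})])
        assert nonconstant_nodes(cs) == ["C"]

    def test_all_free_model_everything_nonconstant(self):
        m = BooleanModel(["a", "b"], {"a": Var("a"), "b": Var("b")})
        assert nonconstant_nodes(solve(m)) == ["a", "b"]

    def test_single_fixed_point_nothing_nonconstant(self):
        cs = CubeSet(["A", "B"], [Cube.make({"A": 1, "B": 0}, set())])
        assert nonconstant_nodes(cs) == []


class TestStandardize:
    def test_balanced_binary_maps_to_plus_minus_one(self):
        x = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        z, kept = standardize(x, ["a", "b"])
        assert kept == ["a", "b"]
        assert set(np.unique(np.round(z, 12))) == {-1.0, 1.0}

    def test_constant_column_dropped(self):
        x = np.array([[0, 1], [1, 1], [0, 1]])
        z, kept = standardize(x, ["a", "b"])
        assert kept == ["a"] and z.shape == (3, 1)

    def test_moments_within_tolerance(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(200, 8))
        z, _ = standardize(x, [f"g{i}" for i in range(8)])
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.ones((5, 3)), ["a", "b", "c"])


class TestClustering:
    def test_planted_clusters_recovered(self):
        """ARI >= 0.99 against planted labels at flip_prob 0.05."""
        states, labels = make_clustered_states(
            n_states=800, n_nodes=40, k=4, flip_prob=0.05, seed=1)
        summary = kmeans_cluster(states, [f"g{i}" for i in range(40)],
                                 k=4, seed=0)
        assert adjusted_rand_score(labels, summary.labels) >= 0.99

    def test_k1_single_cluster(self):
        states, _ = make_clustered_states(50, 10, 2, 0.1, seed=3)
        summary = kmeans_cluster(states, [f"g{i}" for i in range(10)],
                                 k=1, seed=0)
        assert summary.sizes == [50]

    def test_sizes_sum_and_nonempty(self):
        states, _ = make_clustered_states(300, 20, 3, 0.05, seed=5)
        summary = kmeans_cluster(states, [f"g{i}" for i in range(20)],
                                 k=3, seed=2)
        assert sum(summary.sizes) == 300 and min(summary.sizes) > 0
        assert summary.sizes == sorted(summary.sizes, reverse=True)

    def test_row_order_invariance(self):
        states, _ = make_clustered_states(400, 30, 4, 0.05, seed=7)
        cols = [f"g{i}" for i in range(30)]
        s1 = kmeans_cluster(states, cols, k=4, seed=1)
        perm = np.random.default_rng(0).permutation(len(states))
        s2 = kmeans_cluster(states[perm], cols, k=4, seed=1)
        assert adjusted_rand_score(s1.labels[perm], s2.labels) == 1.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.eye(2, dtype=int), ["a", "b"], k=3, seed=0)


class TestGroups:
    def test_two_tight_pairs_merge_as_pairs(self):
        states, labels = make_clustered_states(400, 30, 2, 0.02, seed=11)
        # split each planted cluster in two by adding a weakly varying bit
        summary = kmeans_cluster(states, [f"g{i}" for i in range(30)],
                                 k=4, seed=0)
        mapping = merge_to_groups(summary)
        glabels = summary.group_labels()
        # the 4 k-means clusters must merge back into the 2 planted ones
        assert adjusted_rand_score(labels, glabels) >= 0.99
        assert sorted(set(mapping.values())) == [0, 1]

    def test_k_equals_groups_identity(self):
        states, _ = make_clustered_states(100, 15, 2, 0.05, seed=2)
        summary = kmeans_cluster(states, [f"g{i}" for i in range(15)],
                                 k=2, seed=0)
        assert merge_to_groups(summary, 2) == {0: 0, 1: 1}

    def test_group_rates_are_weighted_cluster_means(self):
        states, _ = make_clustered_states(500, 25, 4, 0.05, seed=4)
        cols = [f"g{i}" for i in range(25)]
        summary = kmeans_cluster(states, cols, k=4, seed=3)
        merge_to_groups(summary)
        table = group_rate_table(states, cols, summary)
        g1_clusters = table.attrs["group1_clusters"]
        sizes = np.array(summary.sizes)
        for _, row in table.iterrows():
            member_rates = [row[f"cluster{c + 1}"] for c in g1_clusters]
            w = sizes[g1_clusters] / sizes[g1_clusters].sum()
            assert row.group1 == pytest.approx(float(np.dot(w, member_rates)))

    def test_marker_orients_group_one(self):
        states, labels = make_clustered_states(300, 20, 2, 0.02, seed=9)
        cols = [f"g{i}" for i in range(20)]
        summary = kmeans_cluster(states, cols, k=2, seed=0)
        merge_to_groups(summary)
        marker = cols[0]
        table = group_rate_table(states, cols, summary, marker=marker)
        row = table[table.node == marker].iloc[0]
        assert row.group1 >= row.group2

    def test_selection_flags(self):
        """A node ON in exactly one group: difference 1.0, selected; a
        node identical across groups: difference 0, ratio 1, unselected."""
        half = 50
        states = np.zeros((2 * half, 5), dtype=int)
        states[:half, 0] = 1      # distinguishes the groups ...
        states[:half, 3] = 1      # ... reinforced by two more columns so
        states[:half, 4] = 1      #     k-means splits on the group axis
        states[:, 1] = 1          # constant -> identical rates
        states[::2, 2] = 1        # same rate in both groups
        cols = ["marker", "always_on", "alternating", "m2", "m3"]
        summary = kmeans_cluster(states, cols, k=2, seed=0)
        merge_to_groups(summary)
        table = group_rate_table(states, cols, summary, marker="marker")
        marker_row = table[table.node == "marker"].iloc[0]
        assert marker_row.difference == pytest.approx(1.0)
        assert bool(marker_row.selected)
        alt = table[table.node == "alternating"].iloc[0]
        assert alt.difference == pytest.approx(0.0)
        assert alt.ratio == pytest.approx(1.0)
        assert not bool(alt.selected)
        assert np.isinf(marker_row.ratio)  # group2 rate is exactly 0


class TestModelConsistency:
    def test_constant_gene_consistency(self):
        cs = CubeSet(["A", "B"], [Cube.make({"A": 1, "B": 1}, set())])
        frac, report = model_consistency(
            cs, ExpressionAnnotation({"A": 1, "B": 0}))
        assert frac == 0.5
        status = dict(zip(report.gene, report.status))
        assert status == {"A": "consistent", "B": "inconsistent"}

    def test_rate_half_is_inconclusive(self):
        cs = CubeSet(["A"], [Cube.make({}, {"A"})])
        frac, report = model_consistency(cs, ExpressionAnnotation({"A": 1}))
        assert np.isnan(frac)
        assert list(report.status) == ["inconclusive"]

    def test_annotation_from_own_rates_is_fully_consistent(self):
        """Annotating each gene with the side its own rate falls on must
        give fraction 1.0 (self-consistency by construction)."""
        for seed in (0, 6, 13):
            m = random_rule_model(seed, n_max=9)
            fps = solve(m)
            if fps.cardinality == 0:
                continue
            rates = rate_of_one(fps)
            annot = ExpressionAnnotation(
                {n: (1 if r > 0.5 else 0) for n, r in rates.items()
                 if r != 0.5})
            if not annot:
                continue
            frac, _ = model_consistency(fps, annot)
            assert frac == 1.0

    def test_absent_gene_skipped_with_report(self):
        cs = CubeSet(["A"], [Cube.make({"A": 1}, set())])
        frac, report = model_consistency(
            cs, ExpressionAnnotation({"A": 1, "ZZZ": 0}))
        assert frac == 1.0
        assert (report[report.gene == "ZZZ"].status == "absent").all()


class TestStatesMatrix:
    def test_full_expansion_when_small(self, mutual_activation):
        fps = solve(mutual_activation)
        mat = states_matrix(fps, cap=10)
        assert mat.shape == (2, 2)

    def test_sampling_when_large(self):
        m = BooleanModel([f"i{j}" for j in range(12)],
                         {f"i{j}": Var(f"i{j}") for j in range(12)})
        fps = solve(m)
        mat = states_matrix(fps, cap=100, seed=0)
        assert mat.shape == (100, 12)
        assert set(np.unique(mat)) <= {0, 1}
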