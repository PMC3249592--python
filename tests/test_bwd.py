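import itertools

import numpy as np
import pytest

from polysuper.bwd import (
    bisection_disconnect,
    bwd_graph,
    bwd_supertree,
    lambda_table,
    primary_evidence,
    support_sac,
    support_sac_max,
)
from polysuper.reconcile import apply_constant
from polysuper.tree import TreeError, parse_newick, topologically_equal

from conftest import random_binary_tree


def trees(*newicks):
    return [parse_newick(s) for s in newicks]


@pytest.fixture
def caterpillar_table():
    return lambda_table(trees("((a:1,b:2):1,c:4);"))


class TestLambdaTable:
    def test_single_tree_distances_to_lca(self, caterpillar_table):
        lt = caterpillar_table
        assert lt.lambda_of("a", "b") == 1.0
        assert lt.lambda_of("b", "a") == 2.0  # asymmetric by construction
        assert lt.lambda_of("a", "c") == 2.0
        assert lt.lambda_of("c", "a") == 4.0

    def test_averaging_across_trees(self):
        lt = lambda_table(trees("((a:1,b:1):1,c:1);", "((a:3,b:1):1,c:1);"))
        assert lt.lambda_of("a", "b") == 2.0
        assert lt.cooccur_of("a", "b") == 2

    def test_noncooccurring_pair_undefined(self):
        lt = lambda_table(trees("((a:1,b:1):1,c:1);", "((d:1,e:1):1,f:1);"))
        assert lt.cooccur_of("a", "d") == 0
        with pytest.raises(TreeError):
            lt.lambda_of("a", "d")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeError):
            lambda_table(trees("((a:1,b),c:1);"))


class TestPrimaryEvidence:
    def test_positive_and_clamped(self, caterpillar_table):
        assert primary_evidence(caterpillar_table, "a", "b", "c") == 1.0
        assert primary_evidence(caterpillar_table, "a", "c", "b") == 0.0

    def test_zero_without_cooccurrence(self):
        lt = lambda_table(trees("((a:1,b:1):1,c:1);", "((d:1,e:1):1,f:1);"))
        assert primary_evidence(lt, "a", "b", "d") == 0.0

    def test_distinct_labels_required(self, caterpillar_table):
        with pytest.raises(TreeError):
            primary_evidence(caterpillar_table, "a", "a", "c")


class TestSupportFunctions:
    def test_hand_evaluated_sac(self, caterpillar_table):
        U = {"a", "b", "c"}
        assert support_sac(caterpillar_table, "a", "b", U) == 1.0
        assert support_sac_max(caterpillar_table, "a", "b", U) == 1.0

    def test_symmetry_and_ordering(self, rng):
        labels = [f"t{i}" for i in range(10)]
        inputs = [
            random_binary_tree(sorted(rng.choice(labels, size=6, replace=False)), rng,
                               with_lengths=True)
            for _ in range(4)
        ]
        lt = lambda_table(inputs)
        taxa = lt.labels
        for x, y in itertools.combinations(taxa, 2):
            sac = support_sac(lt, x, y, taxa)
            assert sac == support_sac(lt, y, x, taxa)
            assert 0.0 <= sac <= support_sac_max(lt, x, y, taxa) + 1e-12

    def test_membership_required(self, caterpillar_table):
        with pytest.raises(TreeError):
            support_sac(caterpillar_table, "a", "z", {"a", "b", "c"})


class TestBwdGraph:
    def test_cross_tree_distance_edge(self):
        # x cooccurs with y (close) and with z (far), never all three together
        inputs = trees("((x:1,y:1):1,q:1);", "((x:5,z:5):1,r:1);")
        g = bwd_graph(inputs, lambda_table(inputs), {"x", "y", "z"})
        assert g.edges.get(frozenset({"x", "y"})) == "distance"
        assert frozenset({"y", "z"}) not in g.edges

    def test_single_tree_adds_no_distance_edges(self):
        inputs = trees("(((a:1,b:1):1,c:1):1,d:1);")
        g = bwd_graph(inputs, lambda_table(inputs), {"a", "b", "c", "d"})
        assert set(g.edges.values()) == {"build"}

    def test_equal_lambda_adds_no_edge(self):
        inputs = trees("((x:2,y:1):1,q:1);", "((x:2,z:5):1,r:1);")
        g = bwd_graph(inputs, lambda_table(inputs), {"x", "y", "z"})
        assert frozenset({"x", "y"}) not in g.edges


class TestBisection:
    def test_removes_lightest_separating_set(self):
        w = {
            frozenset({"a", "b"}): 5.0,
            frozenset({"b", "c"}): 5.0,
            frozenset({"a", "c"}): 2.0,
            frozenset({"a", "d"}): 1.0,
        }
        theta, comps = bisection_disconnect(w, "abcd")
        assert theta == 1.0
        assert comps == [["a", "b", "c"], ["d"]]

    def test_uniform_triangle_shatters(self):
        w = {frozenset(p): 5.0 for p in [("a", "b"), ("b", "c"), ("a", "c")]}
        assert bisection_disconnect(w, "abc") == (5.0, [["a"], ["b"], ["c"]])

    def test_path_cuts_lightest_bridge(self):
        w = {frozenset({"a", "b"}): 3.0, frozenset({"b", "c"}): 7.0}
        assert bisection_disconnect(w, "abc") == (3.0, [["a"], ["b", "c"]])

    def test_matches_exhaustive_threshold_scan(self, rng):
        """theta equals the smallest edge weight whose removal level
        disconnects the graph, by brute force over all distinct weights."""
        for _ in range(40):
            n = int(rng.integers(4, 11))
            labels = [f"v{i}" for i in range(n)]
            weights = {}
            # random connected graph: spanning path plus extras
            for i in range(1, n):
                weights[frozenset({labels[i - 1], labels[i]})] = float(rng.integers(1, 8))
            for _ in range(int(rng.integers(0, 2 * n))):
                i, j = rng.choice(n, size=2, replace=False)
                weights[frozenset({labels[i], labels[j]})] = float(rng.integers(1, 8))

            def components_above(theta):
                import networkx as nx

                g = nx.Graph()
                g.add_nodes_from(labels)
                for e, w in weights.items():
                    if w > theta:
                        g.add_edge(*tuple(e))
                return [sorted(c) for c in nx.connected_components(g)]

            oracle_theta = min(
                w for w in set(weights.values()) if len(components_above(w)) > 1
            )
            theta, comps = bisection_disconnect(weights, labels)
            assert theta == oracle_theta
            assert sorted(comps) == sorted(components_above(theta))

    def test_disconnected_input_is_callers_bug(self):
        with pytest.raises(TreeError):
            bisection_disconnect({frozenset({"a", "b"}): 1.0}, "abc")


class TestBwdSupertree:
    def test_single_binary_input_returned_unchanged(self, rng):
        for n in (5, 8, 12, 16):
            t = random_binary_tree([f"t{i}" for i in range(n)], rng, with_lengths=True)
            assert topologically_equal(bwd_supertree([t]), t)

    def test_duplicate_inputs_behave_like_one(self, rng):
        t = random_binary_tree([f"t{i}" for i in range(10)], rng, with_lengths=True)
        assert topologically_equal(bwd_supertree([t, t.copy()]), t)

    def test_output_is_plenary(self, rng):
        labels = [f"t{i}" for i in range(12)]
        model = random_binary_tree(labels, rng, with_lengths=True)
        from polysuper.tree import restrict

        inputs = [
            restrict(model, sorted(rng.choice(labels, size=8, replace=False)))
            for _ in range(5)
        ]
        st = bwd_supertree(inputs)
        assert st.leaf_labels == set().union(*(t.leaf_labels for t in inputs))

    @pytest.mark.parametrize("support", ["sac", "sacmax"])
    def test_scaling_invariance(self, support, rng):
        labels = [f"t{i}" for i in range(9)]
        inputs = [
            random_binary_tree(sorted(rng.choice(labels, size=6, replace=False)), rng,
                               with_lengths=True)
            for _ in range(4)
        ]
        reference = bwd_supertree(inputs, support=support)
        scaled = bwd_supertree([apply_constant(t, 37.5) for t in inputs], support=support)
        assert topologically_equal(scaled, reference)

    def test_branch_lengths_required(self):
        with pytest.raises(TreeError):
            bwd_supertree(trees("((a,b),c);"))
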