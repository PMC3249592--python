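import math

import numpy as np
import pytest

from polysuper.build import Incompatible, build_supertree
from polysuper.simulate import (
    Alignment,
    GtrParams,
    SimulationConfig,
    add_outgroup,
    count_unrooted_trees,
    default_tree_rate,
    delete_taxa,
    deviate_rates,
    evolve_sequences,
    make_input_trees,
    nj_tree,
    yule_tree,
)
from polysuper.tree import displays, path_length, restrict, topologically_equal
from polysuper.metrics import resolution


class TestYule:
    def test_leaf_count_and_full_resolution(self):
        t = yule_tree(48, seed=1)
        assert t.n_leaves == 48
        assert len(t.clades()) == 46
        assert resolution(t) == 1.0

    def test_deterministic_given_seed(self):
        assert yule_tree(20, seed=5).newick() == yule_tree(20, seed=5).newick()

    @pytest.mark.parametrize("n", [48, 96, 144])
    def test_requested_sizes(self, n):
        assert yule_tree(n, seed=0).n_leaves == n

    def test_ultrametric(self):
        t = yule_tree(15, seed=3)
        depths = set()
        for lab in t.leaf_labels:
            node = t.leaf(lab)
            d = 0.0
            while node.parent is not None:
                d += node.length
                node = node.parent
            depths.add(round(d, 9))
        assert len(depths) == 1


class TestDeviateRates:
    def test_multipliers_inside_truncation(self):
        clock = yule_tree(30, seed=2)
        deviated = deviate_rates(clock, tree_wide_rate=1.0, seed=3)
        orig = {tuple(sorted(clock.clade_of(n))): n.length
                for n in clock.preorder() if n.parent is not None}
        for node in deviated.preorder():
            if node.parent is None:
                continue
            ratio = node.length / orig[tuple(sorted(deviated.clade_of(node)))]
            assert 0.1 <= ratio <= 2.0

    def test_zero_rate_zeroes_lengths(self):
        deviated = deviate_rates(yule_tree(10, seed=2), tree_wide_rate=0.0, seed=0)
        assert all(n.length == 0.0 for n in deviated.preorder() if n.parent is not None)

    def test_mean_multiplier_matches_truncated_normal(self):
        """Empirical mean over many draws agrees with the analytic mean of a
        Normal(1, 0.5) truncated to [0.1, 2.0]."""
        from scipy import stats

        rng = np.random.default_rng(11)
        from polysuper.simulate import _truncated_normal

        draws = np.array([_truncated_normal(rng) for _ in range(100_000)])
        a, b = (0.1 - 1.0) / 0.5, (2.0 - 1.0) / 0.5
        expected = stats.truncnorm.mean(a, b, loc=1.0, scale=0.5)
        assert np.mean(draws) == pytest.approx(expected, abs=3 * draws.std() / math.sqrt(len(draws)))


class TestOutgroup:
    @pytest.fixture
    def model(self):
        return deviate_rates(yule_tree(20, seed=7), default_tree_rate(20), seed=8)

    def test_outgroup_attached_at_root(self, model):
        with_og = add_outgroup(model, "OUT")
        assert with_og.n_leaves == model.n_leaves + 1
        assert frozenset({"OUT"}) in {with_og.clade_of(c) for c in with_og.root.children}

    def test_pendant_length_is_1_25_dmax(self, model):
        with_og = add_outgroup(model, "OUT")
        ingroup = sorted(with_og.leaf_labels - {"OUT"})
        d_max = max(
            path_length(with_og, a, b) for a in ingroup for b in ingroup if a < b
        )
        assert with_og.leaf("OUT").length == pytest.approx(1.25 * d_max)

    def test_removal_recovers_ingroup(self, model):
        with_og = add_outgroup(model, "OUT")
        back = restrict(with_og, with_og.leaf_labels - {"OUT"})
        assert topologically_equal(back, model)

    def test_duplicate_label_rejected(self, model):
        with pytest.raises(Exception):
            add_outgroup(model, sorted(model.leaf_labels)[0])


class TestDeleteTaxa:
    def test_deletion_arithmetic(self):
        t = add_outgroup(deviate_rates(yule_tree(48, seed=1), 0.01, seed=2), "OUT")
        kept = delete_taxa(t, 0.25, seed=3, keep={"OUT"})
        assert kept.n_leaves == 36 + 1

    def test_zero_ratio_is_identity(self):
        t = yule_tree(10, seed=4)
        assert topologically_equal(delete_taxa(t, 0.0, seed=0), t)

    def test_outgroup_always_retained(self):
        t = add_outgroup(deviate_rates(yule_tree(12, seed=1), 0.01, seed=2), "OUT")
        for seed in range(5):
            assert "OUT" in delete_taxa(t, 0.5, seed=seed, keep={"OUT"}).leaf_labels


class TestGtr:
    def test_rate_matrix_is_proper_and_reversible(self):
        params = GtrParams()
        Q = params.rate_matrix()
        pi = np.array(params.freqs)
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T)  # detailed balance
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GtrParams(freqs=(0.5, 0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            GtrParams(gamma_shape=-1)


class TestEvolveSequences:
    @pytest.fixture
    def small_tree(self):
        return deviate_rates(yule_tree(6, seed=9), 0.3, seed=10)

    def test_all_invariant_sites_copy_the_root(self, small_tree):
        params = GtrParams(p_invariant=0.999999)
        aln = evolve_sequences(small_tree, 300, params, seed=1)
        seqs = list(aln.sequences.values())
        assert all(np.array_equal(seqs[0], s) for s in seqs[1:])

    def test_stationary_base_composition(self, small_tree):
        params = GtrParams()
        aln = evolve_sequences(small_tree, 60_000, params, seed=2)
        counts = np.zeros(4)
        for seq in aln.sequences.values():
            counts += np.bincount(seq, minlength=4)
        freqs = counts / counts.sum()
        assert np.allclose(freqs, params.freqs, atol=0.01)

    def test_deterministic_given_seed(self, small_tree):
        a1 = evolve_sequences(small_tree, 200, GtrParams(), seed=3)
        a2 = evolve_sequences(small_tree, 200, GtrParams(), seed=3)
        assert all(np.array_equal(a1.sequences[t], a2.sequences[t]) for t in a1.taxa)


class TestNjTree:
    def test_recovers_easy_quartet(self):
        from polysuper.tree import parse_newick

        model = parse_newick("(((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.3):0.05,OUT:0.9);")
        aln = evolve_sequences(model, 4000, GtrParams(), seed=5)
        t = nj_tree(aln, "OUT")
        assert topologically_equal(t, parse_newick("((a,b),(c,d));"))

    def test_three_taxa_rooted_pair(self):
        from polysuper.tree import parse_newick

        model = parse_newick("((a:0.1,b:0.1):0.4,OUT:1.0);")
        aln = evolve_sequences(model, 1000, GtrParams(), seed=6)
        t = nj_tree(aln, "OUT")
        assert t.leaf_labels == {"a", "b"}

    def test_input_order_invariance(self):
        from polysuper.tree import parse_newick

        model = parse_newick("(((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2):0.1,OUT:1.0);")
        aln = evolve_sequences(model, 2000, GtrParams(), seed=7)
        shuffled = Alignment(dict(reversed(list(aln.sequences.items()))))
        assert topologically_equal(nj_tree(aln, "OUT"), nj_tree(shuffled, "OUT"))


class TestMakeInputTrees:
    def test_clean_restriction_zero_deletion_equals_model(self):
        cfg = SimulationConfig(n_taxa=12, deletion_ratio=0.0, n_input_trees=3, seed=1)
        model, inputs = make_input_trees(cfg)
        for t in inputs:
            assert topologically_equal(t, model)

    def test_deletion_arithmetic_per_input(self):
        cfg = SimulationConfig(n_taxa=96, deletion_ratio=0.5, n_input_trees=4, seed=2)
        model, inputs = make_input_trees(cfg)
        assert model.n_leaves == 97
        for t in inputs:
            assert t.n_leaves == 48 + 1  # half the ingroup plus the outgroup

    def test_clean_restrictions_are_compatible(self):
        cfg = SimulationConfig(n_taxa=16, deletion_ratio=0.25, n_input_trees=5, seed=3)
        model, inputs = make_input_trees(cfg)
        st = build_supertree(inputs)
        assert not isinstance(st, Incompatible)
        for t in inputs:
            assert displays(st, t)

    def test_replicates_reproducible(self):
        cfg = SimulationConfig(n_taxa=10, deletion_ratio=0.25, n_input_trees=3, seed=4)
        m1, i1 = make_input_trees(cfg)
        m2, i2 = make_input_trees(cfg)
        assert m1.newick() == m2.newick()
        assert [t.newick() for t in i1] == [t.newick() for t in i2]

    def test_sequence_mode_produces_ingroup_trees(self):
        cfg = SimulationConfig(
            n_taxa=12, deletion_ratio=0.25, n_input_trees=2,
            input_mode="sequence_nj", block_length=500, seed=5,
        )
        model, inputs = make_input_trees(cfg)
        for t in inputs:
            assert "OUT" not in t.leaf_labels
            assert t.leaf_labels <= model.leaf_labels
            assert t.has_branch_lengths()


class TestTreeCount:
    def test_tiny_cases(self):
        assert count_unrooted_trees(3).exact == 1
        assert count_unrooted_trees(4).exact == 3

    def test_double_factorial_recurrence(self):
        prev = count_unrooted_trees(4).exact
        for n in range(5, 21):
            cur = count_unrooted_trees(n).exact
            assert cur == prev * (2 * n - 5)
            prev = cur

    def test_mantissa_matches_exact_value(self):
        tc = count_unrooted_trees(200)
        digits = str(tc.exact)
        assert tc.exponent == len(digits) - 1
        assert tc.mantissa == round(float(digits[0] + "." + digits[1:6]), 1)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            count_unrooted_trees(2)
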