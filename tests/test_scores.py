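"""Fair Proportion, Shapley, and HED: frozen examples, identities, limits."""

import numpy as np
import pandas as pd
import pytest

from phylodist import (
    ExtinctionMap,
    TaxonSetError,
    TraversalStats,
    ValidationError,
    compute_leaf_ordering,
    edge_product,
    fair_proportion,
    hed_linear,
    hed_quadratic,
    hed_zero_prob,
    parse_newick,
    pendant_lengths,
    random_probabilities,
    score_table,
    shapley_linear,
    shapley_quadratic,
    subtree_products,
    yule_tree,
)

from conftest import max_rel_err


class TestFairProportion:
    def test_balanced_quartet_all_equal(self, quartet):
        fp = fair_proportion(quartet)
        assert fp.tolist() == [1.5, 1.5, 1.5, 1.5]
        assert fp.sum() == quartet.total_length

    def test_caterpillar_path_sums(self, caterpillar):
        fp = fair_proportion(caterpillar)
        assert fp["d"] == pytest.approx(3.0)
        assert fp["c"] == pytest.approx(2 + 1 / 3)
        assert fp["a"] == pytest.approx(1 + 1 / 2 + 1 / 3)
        assert fp["a"] == fp["b"]

    def test_conservation_on_random_trees(self):
        for seed in range(5):
            t = yule_tree(60, seed=seed)
            assert fair_proportion(t).sum() == pytest.approx(
                t.total_length, rel=1e-9
            )

    def test_unrooted_input_rejected(self, quartet_unrooted):
        with pytest.raises(ValidationError, match="root"):
            fair_proportion(quartet_unrooted)


class TestShapley:
    def test_quartet_symmetry(self, quartet):
        sh = shapley_linear(quartet)
        assert sh.tolist() == pytest.approx([1.5] * 4)

    def test_two_leaf_half_edge_each(self, two_leaf):
        assert shapley_linear(two_leaf).tolist() == pytest.approx([1.5, 1.5])

    def test_efficiency_sum_is_total_length(self):
        t = yule_tree(150, seed=9)
        assert shapley_linear(t).sum() == pytest.approx(
            t.unrooted().total_length, rel=1e-9
        )

    def test_linear_matches_quadratic_midscale(self):
        t = yule_tree(200, seed=21)
        assert max_rel_err(shapley_linear(t), shapley_quadratic(t)) <= 1e-9

    def test_rerooting_invariance(self):
        t = yule_tree(50, seed=2).unrooted()
        base = shapley_linear(t)
        for e in (0, 5, 17):
            s = shapley_linear(t.rooted_on_edge(e, 0.3)).reindex(base.index)
            assert max_rel_err(s, base) <= 1e-9

    def test_scale_equivariance(self):
        t = yule_tree(40, seed=3)
        assert max_rel_err(shapley_linear(t.scaled(7.3)), 7.3 * shapley_linear(t)) <= 1e-9

    def test_update_counter_within_linear_bound(self):
        for seed, n in ((0, 10), (1, 100), (2, 500)):
            t = yule_tree(n, seed=seed)
            st = TraversalStats()
            shapley_linear(t, st)
            assert st.edge_updates <= 2 * st.num_edges


class TestHed:
    def test_quartet_uniform_half(self, quartet):
        p = ExtinctionMap.uniform(quartet.taxa, 0.5)
        hed = hed_linear(quartet, p)
        assert hed.tolist() == pytest.approx([2.0] * 4)

    def test_all_prob_one_gives_zero(self):
        t = yule_tree(30, seed=5)
        hed = hed_linear(t, ExtinctionMap.uniform(t.taxa, 1.0))
        assert np.max(np.abs(hed.to_numpy())) == 0.0

    def test_all_prob_zero_gives_pendant_lengths(self):
        t = yule_tree(30, seed=6)
        hed = hed_linear(t, ExtinctionMap.uniform(t.taxa, 0.0))
        assert np.max(np.abs((hed - pendant_lengths(t)).to_numpy())) <= 1e-12

    def test_small_uniform_p_converges_to_pendant(self):
        """As a uniform p shrinks toward 0, HED collapses onto the pendant
        edge length (deeper edges are damped like p^(k-1))."""
        t = yule_tree(25, seed=8)
        pend = pendant_lengths(t).to_numpy()
        gaps = []
        for p in (0.1, 1e-3, 1e-6):
            cur = hed_linear(t, ExtinctionMap.uniform(t.taxa, p)).to_numpy()
            gaps.append(float(np.max(np.abs(cur - pend))))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] <= 1e-4

    def test_linear_matches_quadratic_with_zeros(self):
        t = yule_tree(200, seed=13)
        p = random_probabilities(t.taxa, "uniform01", seed=1, n_zeros=4)
        assert max_rel_err(hed_linear(t, p), hed_quadratic(t, p)) <= 1e-9

    def test_zero_prob_route_matches_edge_formula(self, quartet):
        p = {"a": 0.0, "b": 0.5, "c": 0.5, "d": 0.5}
        # direct edge-sum of the HED definition for taxon a
        # pendant a: 1*(1-0.125)*1 ; internal: 0.5*0.75*2 ; pendants b,c,d
        expected = 0.875 + 0.75 + 0.25 * 0.5 * 1 * 3
        assert hed_zero_prob(quartet, p, "a") == pytest.approx(expected)
        assert hed_linear(quartet, p)["a"] == pytest.approx(expected)

    def test_two_zero_taxa_blocks_shared_splits(self, quartet):
        p = {"a": 0.0, "b": 0.0, "c": 0.5, "d": 0.5}
        got = hed_linear(quartet, p)
        ref = hed_quadratic(quartet, p)
        assert max_rel_err(got, ref) <= 1e-12

    def test_zero_prob_route_rejects_positive_p(self, quartet):
        p = ExtinctionMap.uniform(quartet.taxa, 0.5)
        with pytest.raises(ValidationError, match="p > 0"):
            hed_zero_prob(quartet, p, "a")

    def test_missing_and_invalid_probabilities_rejected(self, quartet):
        with pytest.raises(TaxonSetError, match="d"):
            hed_linear(quartet, {"a": 0.1, "b": 0.1, "c": 0.1})
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            hed_linear(quartet, {"a": 0.1, "b": 1.5, "c": 0.1, "d": 0.1})

    def test_rerooting_invariance(self):
        t = yule_tree(50, seed=14).unrooted()
        p = random_probabilities(t.taxa, "uniform01", seed=2, n_zeros=1)
        base = hed_linear(t, p)
        for e in (1, 9, 33):
            got = hed_linear(t.rooted_on_edge(e, 0.7), p).reindex(base.index)
            assert max_rel_err(got, base) <= 1e-9


class TestEdgeProduct:
    def test_products(self):
        fp = pd.Series({"a": 1.5, "b": 2.0})
        got = edge_product(fp, {"a": 0.4, "b": 0.0})
        assert got["a"] == pytest.approx(0.6)
        assert got["b"] == 0.0

    def test_p_one_is_identity(self):
        fp = pd.Series({"a": 1.5, "b": 2.0})
        assert edge_product(fp, {"a": 1.0, "b": 1.0}).tolist() == [1.5, 2.0]

    def test_mismatch_lists_symmetric_difference(self):
        fp = pd.Series({"a": 1.5, "b": 2.0})
        with pytest.raises(TaxonSetError, match="c"):
            edge_product(fp, {"a": 0.1, "c": 0.2})


class TestLeafOrdering:
    def test_quartet_order_and_paths(self, quartet):
        lo = compute_leaf_ordering(quartet)
        assert lo.labels == ("a", "b", "c", "d")
        assert len(lo.between(0)) == 2
        assert len(lo.between(1)) == 4
        assert len(lo.between(2)) == 2

    def test_each_edge_in_at_most_two_paths(self):
        t = yule_tree(40, seed=17)
        lo = compute_leaf_ordering(t)
        counts = {}
        for i in range(len(lo.labels) - 1):
            for e in lo.between(i):
                counts[e] = counts.get(e, 0) + 1
        assert max(counts.values()) <= 2

    def test_two_leaf_tree(self, two_leaf):
        lo = compute_leaf_ordering(two_leaf.unrooted())
        assert lo.labels == ("a", "b")
        assert len(lo.between(0)) == 1


class TestSubtreeProducts:
    def test_quartet_pendant_products(self, quartet_unrooted):
        t = quartet_unrooted
        p = ExtinctionMap.uniform(t.taxa, 0.5)
        prods = subtree_products(t, p)
        e = t.pendant_edge("a")
        lo_is_leaf = t.is_leaf_vertex(t.edge_endpoints(e)[1])
        below = prods.below_plain(e)
        above = prods.above_plain(e)
        leaf_side, other_side = (below, above) if lo_is_leaf else (above, below)
        assert leaf_side == pytest.approx(0.5)
        assert other_side == pytest.approx(0.125)

    def test_zero_bookkeeping(self, quartet_unrooted):
        t = quartet_unrooted
        p = {"a": 0.0, "b": 0.5, "c": 0.5, "d": 0.5}
        prods = subtree_products(t, p)
        e = t.pendant_edge("a")
        assert prods.below_plain(e) * prods.above_plain(e) == 0.0
        assert prods.below_zc[e] + prods.above_zc[e] == 1

    def test_sides_factorise_total(self):
        t = yule_tree(20, seed=19).unrooted()
        p = random_probabilities(t.taxa, "uniform01", seed=3)
        total = float(np.prod([p[x] for x in t.taxa]))
        prods = subtree_products(t, p)
        for e in range(t.num_edges):
            assert prods.below_plain(e) * prods.above_plain(e) == pytest.approx(
                total, rel=1e-9
            )


class TestScoreTable:
    def test_columns_and_row_order(self, quartet):
        p = ExtinctionMap.uniform(quartet.taxa, 0.5)
        df = score_table(quartet, ("fp", "shapley", "hed", "edge"), p=p)
        assert list(df.columns) == ["fp", "shapley", "hed", "edge", "pendant"]
        assert list(df.index) == list(quartet.taxa)
        assert df["edge"].tolist() == pytest.approx([0.75] * 4)

    def test_hed_without_probabilities_rejected(self, quartet):
        with pytest.raises(ValidationError, match="probabilit"):
            score_table(quartet, ("hed",))
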