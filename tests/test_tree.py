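"""Tree structure, Newick round-trips, splits, and phylogenetic diversity."""

import math

import pytest

from phylodist import (
    NewickParseError,
    TaxonSetError,
    ValidationError,
    parse_newick,
    phylogenetic_diversity,
    split_of_edge,
    write_newick,
    yule_tree,
)


class TestParse:
    def test_structure_of_balanced_quartet(self, quartet):
        assert quartet.n == 4
        assert quartet.num_edges == 6
        assert quartet.total_length == 6.0
        assert quartet.is_rooted
        assert quartet.taxa == ("a", "b", "c", "d")

    def test_two_leaf_tree_has_degree_two_root(self, two_leaf):
        assert two_leaf.n == 2
        assert two_leaf.degree(two_leaf.root) == 2
        assert two_leaf.total_length == 3.0

    def test_root_stem_length_is_stored_but_not_counted(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1):5;")
        assert t.root_edge_length == 5.0
        assert t.total_length == 6.0

    def test_internal_labels_ignored_quoted_and_underscore_labels_kept(self):
        t = parse_newick("(('sp one':1,b_x:1)node7:1,c:2);")
        assert set(t.taxa) == {"sp one", "b_x", "c"}

    @pytest.mark.parametrize(
        "bad",
        ["((a:1,b:1:1,c:1);", "", "(a:1,b:1", "not a tree"],
    )
    def test_malformed_input_raises_parse_error(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_label_raises_naming_it(self):
        with pytest.raises(ValidationError, match="[dD]uplicate"):
            parse_newick("((a:1,a:1):1,c:1);")

    def test_missing_branch_length_raises(self):
        with pytest.raises(ValidationError, match="branch length"):
            parse_newick("((a:1,b):1,c:1);")

    def test_negative_branch_length_raises(self):
        with pytest.raises(ValidationError, match="egative"):
            parse_newick("((a:1,b:-0.5):1,c:1);")

    def test_single_taxon_rejected(self):
        with pytest.raises((ValidationError, NewickParseError)):
            parse_newick("(a:1);")

    def test_unifurcation_rejected_off_root(self):
        with pytest.raises(ValidationError, match="degree-2"):
            parse_newick("(((a:1):1,b:1):1,c:1);")

    def test_polytomies_supported(self):
        t = parse_newick("(a:1,b:1,c:1,d:1,e:1);")
        assert t.n == 5
        assert t.num_edges == 5

    def test_zero_length_edges_are_legal(self):
        t = parse_newick("((a:0,b:1):0,c:1);")
        assert t.total_length == 2.0


class TestRoundTrip:
    @pytest.mark.parametrize(
        "text",
        [
            "((a:1,b:1):1,(c:1,d:1):1);",
            "(a:1,b:2);",
            "(((a:1,b:1):1,c:2):1,d:3);",
            "(a:1,b:1,c:1,(d:0.5,e:2.25):1);",
        ],
    )
    def test_write_then_parse_is_identity(self, text):
        t = parse_newick(text)
        t2 = parse_newick(write_newick(t))
        assert t2.taxa == t.taxa
        assert t2.total_length == pytest.approx(t.total_length, rel=0, abs=0)
        assert write_newick(t2) == write_newick(t)

    def test_unrooted_write_has_no_degree_two_vertices(self, quartet):
        u = quartet.unrooted()
        t2 = parse_newick(write_newick(u))
        assert t2.degree(t2.root) == 3

    def test_root_stem_survives_round_trip(self):
        t = parse_newick("((a:1,b:1):1,c:2):5;")
        assert parse_newick(write_newick(t)).root_edge_length == 5.0


class TestUnroot:
    def test_degree_two_root_suppressed_lengths_merged(self, quartet):
        u = quartet.unrooted()
        assert not u.is_rooted
        assert u.num_edges == 5
        assert u.total_length == 6.0
        assert sorted(u.pendant_lengths().values()) == [1, 1, 1, 1]
        internal = [u.edge_length(e) for e in range(5)
                    if not (u.is_leaf_vertex(u.edge_endpoints(e)[0])
                            or u.is_leaf_vertex(u.edge_endpoints(e)[1]))]
        assert internal == [2.0]

    def test_two_leaf_tree_collapses_to_single_edge(self, two_leaf):
        u = two_leaf.unrooted()
        assert u.num_edges == 1
        assert u.edge_length(0) == 3.0

    def test_trifurcating_root_unchanged(self):
        t = parse_newick("(a:1,b:1,c:1);")
        u = t.unrooted()
        assert u.num_edges == t.num_edges
        assert u.total_length == t.total_length
        assert not u.is_rooted

    def test_unroot_preserves_splits(self, quartet):
        u = quartet.unrooted()
        blocks = set()
        for e in range(u.num_edges):
            s = split_of_edge(u, e, "a")
            blocks.add(frozenset(s.co_block))
        assert frozenset({"c", "d"}) in blocks


class TestPD:
    def test_quartet_same_side_pair(self, quartet_unrooted):
        assert phylogenetic_diversity(quartet_unrooted, ["a", "b"]) == 2.0

    def test_quartet_cross_pair(self, quartet_unrooted):
        assert phylogenetic_diversity(quartet_unrooted, ["a", "c"]) == 4.0

    def test_full_set_is_total_length(self, quartet_unrooted):
        assert phylogenetic_diversity(
            quartet_unrooted, quartet_unrooted.taxa
        ) == quartet_unrooted.total_length

    def test_empty_and_singleton_are_zero(self, quartet_unrooted):
        assert phylogenetic_diversity(quartet_unrooted, []) == 0.0
        assert phylogenetic_diversity(quartet_unrooted, ["a"]) == 0.0

    def test_unknown_taxon_named_in_error(self, quartet_unrooted):
        with pytest.raises(TaxonSetError, match="zz"):
            phylogenetic_diversity(quartet_unrooted, ["a", "zz"])

    def test_monotone_in_subset(self):
        t = yule_tree(20, seed=4)
        taxa = list(t.taxa)
        prev = 0.0
        for k in range(1, len(taxa) + 1):
            cur = phylogenetic_diversity(t, taxa[:k])
            assert cur >= prev - 1e-12
            prev = cur


class TestSplit:
    def test_pendant_edge_isolates_leaf(self, quartet):
        e = quartet.pendant_edge("a")
        s = split_of_edge(quartet, e, "a")
        assert s.block == frozenset({"a"})
        assert s.co_size == 3

    def test_reference_on_far_side(self, quartet):
        e = quartet.pendant_edge("b")
        s = split_of_edge(quartet, e, "a")
        assert s.block == frozenset({"a", "c", "d"})

    def test_block_sizes_sum_to_n(self, quartet):
        for e in range(quartet.num_edges):
            s = split_of_edge(quartet, e, "c")
            assert s.size + s.co_size == quartet.n
            assert "c" in s.block


class TestRerootScale:
    def test_scaled_multiplies_lengths(self, quartet):
        assert quartet.scaled(2.5).total_length == 15.0
        with pytest.raises(ValidationError):
            quartet.scaled(-1.0)

    def test_rooted_on_edge_splits_length(self, quartet_unrooted):
        t = quartet_unrooted.rooted_on_edge(0, 0.25)
        assert t.is_rooted
        assert t.degree(t.root) == 2
        assert t.total_length == pytest.approx(quartet_unrooted.total_length)
        # unrooting recovers the original edge count
        assert t.unrooted().num_edges == quartet_unrooted.num_edges

    def test_restricted_to_merges_lengths(self):
        t = parse_newick("((a:1,b:1):1,((c:1,x:1):1,d:2):1);")
        r = t.restricted_to(["a", "c", "d"])
        assert set(r.taxa) == {"a", "c", "d"}
        assert r.pendant_lengths()["a"] == 2.0  # 1 + merged clade edge 1
        assert r.total_length == 7.0
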