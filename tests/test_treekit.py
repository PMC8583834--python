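"""Tree model: parsing, collapsing, splits, monophyly, ages, grouping."""

import pytest

import _oracles as orc
from phylodup import treekit as tk


class TestParseNewick:
    def test_seven_tip_plastid_topology_has_ingroup_clade(self):
        t = tk.parse_newick("((F,(((A,B),C),(E,D))),G);")
        assert len(tk.tip_labels(t)) == 7
        assert tk.is_monophyletic(t, set("ABCDE"))

    def test_two_tip_tree(self):
        t = tk.parse_newick("(A,B);")
        assert tk.tip_labels(t) == frozenset("AB")
        assert sum(1 for _ in t.preorder_internal_node_iter()) == 1

    def test_supports_and_lengths_read_back(self):
        t = tk.parse_newick("((A:1,B:1)0.98:1,C:2);")
        internal = [
            nd for nd in t.preorder_internal_node_iter() if nd.parent_node
        ]
        assert internal[0].support == pytest.approx(0.98)
        lengths = sorted(
            nd.edge.length for nd in t.preorder_node_iter() if nd.parent_node
        )
        assert lengths == [1.0, 1.0, 1.0, 2.0]

    def test_percentage_supports_rescaled(self):
        t = tk.parse_newick("((A,B)87:1,C);")
        internal = [
            nd for nd in t.preorder_internal_node_iter() if nd.parent_node
        ]
        assert internal[0].support == pytest.approx(0.87)

    @pytest.mark.parametrize("bad", ["((A,B);", "((A,B),A);", "(A,(B,C)));"])
    def test_malformed_or_duplicate_input_raises(self, bad):
        with pytest.raises(tk.NewickParseError):
            tk.parse_newick(bad)

    def test_roundtrip_identity_on_random_trees(self, rnd):
        for i in range(20):
            n = rnd.randint(3, 10)
            labels = [f"t{k}" for k in range(n)]
            t = tk.random_binary_tree(labels, rnd, ultrametric=True, depth=5.0)
            for nd in t.preorder_internal_node_iter():
                if nd.parent_node:
                    nd.support = round(rnd.random(), 3)
            back = tk.parse_newick(tk.write_newick(t))
            assert tk.bipartitions(back) == tk.bipartitions(t)
            assert {
                frozenset(l.taxon.label for l in nd.leaf_iter()): nd.support
                for nd in t.preorder_internal_node_iter()
            } == {
                frozenset(l.taxon.label for l in nd.leaf_iter()): nd.support
                for nd in back.preorder_internal_node_iter()
            }
            assert tk.tmrca(back, set(labels)) == pytest.approx(
                tk.tmrca(t, set(labels)), rel=1e-9
            )


class TestCollapseLowSupport:
    def test_low_support_node_becomes_polytomy(self):
        out = tk.collapse_low_support(tk.parse_newick("((A,B)0.5,C);"), 0.97)
        assert tk.bipartitions(out) == frozenset()
        assert tk.tip_labels(out) == frozenset("ABC")

    def test_high_support_node_kept(self):
        t = tk.parse_newick("((A,B)0.99,C);")
        out = tk.collapse_low_support(t, 0.97)
        assert tk.bipartitions(out) == tk.bipartitions(t)

    def test_exact_threshold_support_is_kept(self):
        # "lower than" is strict: support == threshold survives
        out = tk.collapse_low_support(
            tk.parse_newick("(((A,B)0.97,C)0.969,D);"), 0.97
        )
        assert tk.bipartitions(out) == tk.bipartitions(
            tk.parse_newick("((A,B),C,D);")
        )

    def test_unsupported_nodes_never_collapsed(self):
        t = tk.parse_newick("((A,B),C);")
        out = tk.collapse_low_support(t, 0.97)
        assert tk.write_newick(out).count("(") == 2

    def test_matches_split_filter_oracle_and_idempotent(self, rnd):
        for _ in range(15):
            labels = [f"t{k}" for k in range(10)]
            t = tk.random_binary_tree(labels, rnd)
            sups = {}
            for nd in t.preorder_internal_node_iter():
                if nd.parent_node:
                    nd.support = round(rnd.random(), 2)
                    side = frozenset(l.taxon.label for l in nd.leaf_iter())
                    sups[tk.canonical_split(side, frozenset(labels))] = nd.support
            out = tk.collapse_low_support(t, 0.97)
            expected = {
                s
                for s in tk.bipartitions(t)
                if sups.get(s) is None or sups[s] >= 0.97
            }
            assert tk.bipartitions(out) == frozenset(expected)
            again = tk.collapse_low_support(out, 0.97)
            assert tk.bipartitions(again) == tk.bipartitions(out)


class TestBipartitions:
    def test_root_split_counted_once(self):
        t = tk.parse_newick("((A,B),(C,D));")
        assert tk.bipartitions(t) == frozenset({frozenset("CD")})

    def test_star_tree_has_no_splits(self):
        assert tk.bipartitions(tk.parse_newick("(A,B,C);")) == frozenset()

    def test_caterpillar_five_tips_has_two_splits(self):
        t = tk.parse_newick("((((A,B),C),D),E);")
        assert len(tk.bipartitions(t)) == 2

    def test_matches_independent_enumeration(self, rnd):
        for _ in range(20):
            n = rnd.randint(4, 9)
            t = tk.random_binary_tree([f"t{k}" for k in range(n)], rnd)
            nwk = tk.write_newick(t)
            assert tk.bipartitions(t) == orc.splits(orc.parse(nwk))


class TestRFDistance:
    def test_identical_trees(self):
        t = tk.parse_newick("((A,B),(C,(D,E)));")
        assert tk.rf_distance(t, tk.parse_newick("((A,B),(C,(D,E)));")) == 0

    def test_polytomy_vs_resolved(self):
        t1 = tk.parse_newick("((A,B),C,(D,E));")
        t2 = tk.parse_newick("(((A,B),C),(D,E));")
        assert tk.rf_distance(t1, t2) == len(
            orc.splits(orc.parse("((A,B),C,(D,E));"))
            ^ orc.splits(orc.parse("(((A,B),C),(D,E));"))
        )

    def test_tip_mismatch_names_offenders(self):
        with pytest.raises(tk.TipSetMismatchError, match="D"):
            tk.rf_distance(
                tk.parse_newick("((A,B),C);"), tk.parse_newick("((A,B),D);")
            )

    def test_matches_oracle_and_is_a_metric(self, rnd):
        labels = [f"t{k}" for k in range(6)]
        trees = [tk.random_binary_tree(labels[:], rnd) for _ in range(12)]
        for t in trees:
            assert tk.rf_distance(t, t) == 0
        for a in trees[:6]:
            for b in trees[6:]:
                d = tk.rf_distance(a, b)
                assert d == orc.rf(
                    orc.parse(tk.write_newick(a)), orc.parse(tk.write_newick(b))
                )
                assert d == tk.rf_distance(b, a)
        for a, b, c in zip(trees[:4], trees[4:8], trees[8:]):
            assert tk.rf_distance(a, c) <= tk.rf_distance(a, b) + tk.rf_distance(b, c)


class TestMonophyly:
    def test_plastid_ingroup_monophyletic(self):
        t = tk.parse_newick("((F,(((A,B),C),(E,D))),G);")
        assert tk.is_monophyletic(t, set("ABCDE"))

    def test_xdh_ingroup_not_monophyletic(self):
        t = tk.parse_newick("((((A,B),(C),E),(D),(F)),G);")
        assert not tk.is_monophyletic(t, set("ABCDE"))

    def test_full_tip_set_is_monophyletic(self):
        t = tk.parse_newick("((A,B),(C,D));")
        assert tk.is_monophyletic(t, set("ABCD"))

    def test_unknown_taxon_raises(self):
        with pytest.raises(tk.UnknownTaxonError):
            tk.is_monophyletic(tk.parse_newick("((A,B),C);"), {"A", "Z"})


class TestTmrca:
    def test_cherry(self):
        assert tk.tmrca(tk.parse_newick("(A:10,B:10);"), {"A", "B"}) == 10

    def test_spanning_pair_hits_root(self):
        t = tk.parse_newick("((A:5,B:5):5,C:10);")
        assert tk.tmrca(t, {"A", "C"}) == pytest.approx(10)
        assert tk.tmrca(t, {"A", "B"}) == pytest.approx(5)

    def test_non_ultrametric_raises(self):
        with pytest.raises(tk.NonUltrametricError):
            tk.tmrca(tk.parse_newick("(A:1,B:2);"), {"A", "B"})

    def test_equals_bruteforce_min_ancestral_age(self, rnd):
        for _ in range(10):
            labels = [f"t{k}" for k in range(7)]
            t = tk.random_binary_tree(labels, rnd, ultrametric=True, depth=10)
            ages = tk.node_ages(t)
            taxa = set(rnd.sample(labels, rnd.randint(2, 6)))
            want = min(
                ages[nd]
                for nd in t.preorder_internal_node_iter()
                if taxa <= {l.taxon.label for l in nd.leaf_iter()}
            )
            assert tk.tmrca(t, taxa) == pytest.approx(want)


class TestToGroupTree:
    def test_species_level_reduces_to_seven_groups(self):
        sp = {c: [f"{c.lower()}{i}" for i in range(3)] for c in "ABCDEFG"}
        gm = tk.group_map_for_species(sp)
        nwk = "((({a},{b}),({c},{d})),(({e},{f}),{g}));".format(
            a="({},{},{})".format(*sp["A"]),
            b="({},{},{})".format(*sp["B"]),
            c="({},{},{})".format(*sp["C"]),
            d="({},{},{})".format(*sp["D"]),
            e="({},{},{})".format(*sp["E"]),
            f="({},{},{})".format(*sp["F"]),
            g="({},{},{})".format(*sp["G"]),
        )
        gt = tk.to_group_tree(tk.parse_newick(nwk), gm)
        assert tk.tip_labels(gt) == frozenset("ABCDEFG")
        assert tk.is_monophyletic(gt, {"A", "B"})

    def test_single_tip_group_passes_through(self, groups):
        t = tk.parse_newick("((F,(((A,B),C),(E,D))),G);")
        gt = tk.to_group_tree(t, groups)
        assert tk.rf_distance(gt, t) == 0

    def test_paraphyletic_group_is_named_in_error(self):
        gm = tk.group_map_for_species({"A": ["a1", "a2"], "B": ["b1"]})
        with pytest.raises(tk.NonMonophyleticGroupError, match="A"):
            tk.to_group_tree(tk.parse_newick("((a1,b1),a2);"), gm)
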