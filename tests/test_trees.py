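import numpy as np
import pytest

from hybcoal.trees import (GeneTreeSample, ParentalTree, TreeError,
                           NewickParseError, enumerate_rooted_topologies,
                           is_binary, load_taxon_map, parse_newick,
                           resolve_polytomies, root_on_outgroup,
                           semi_strict_consensus, write_newick)

from conftest import random_topology


class TestNewick:
    def test_parse_basic(self):
        t = parse_newick("((a,b),c);")
        assert t.tip_labels == {"a", "b", "c"}
        assert t.is_binary()

    def test_lengths_discarded_by_default(self):
        t = parse_newick("((a:0.1,b:0.2):0.3,c:0.5);")
        assert t == parse_newick("((a,b),c);")
        assert all(n.length is None for n in t.postorder())

    def test_lengths_kept_on_request(self):
        t = parse_newick("((a:0.1,b:0.2):0.3,c:0.5);",
                         expect_branch_lengths=True)
        assert any(n.length is not None for n in t.postorder())

    @pytest.mark.parametrize("bad", ["((a,b),c;", "((a,b)),c;", "a b c"])
    def test_malformed(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((a,a),c);")

    @pytest.mark.parametrize("n_tips", [4, 8, 20])
    def test_roundtrip_random_trees(self, n_tips):
        rng = np.random.default_rng(n_tips)
        for _ in range(10):
            t = random_topology([f"t{i}" for i in range(n_tips)], rng)
            back = parse_newick(write_newick(t))
            assert set(back.clades()) == set(t.clades())


class TestTaxonMap:
    def test_load(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("# comment\nSca151\tcatenatus\nScter16\ttergeminus\n")
        m = load_taxon_map(str(p))
        assert len(m) == 2
        assert m.species_of("Sca151") == "catenatus"

    def test_duplicate_row_deduplicated(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("x\tA\nx\tA\ny\tB\n")
        assert len(load_taxon_map(str(p))) == 2

    def test_conflicting_assignment_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("x\tA\nx\tB\n")
        with pytest.raises(TreeError):
            load_taxon_map(str(p))

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("# nothing\n")
        with pytest.raises(TreeError):
            load_taxon_map(str(p))


class TestConsensus:
    def test_idempotent(self):
        t = parse_newick("((a,b),(c,d));")
        assert semi_strict_consensus([t, t]) == t

    def test_compatible_resolution_retained(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),c,d);")
        assert semi_strict_consensus([t1, t2]) == t1

    def test_conflict_collapses_to_star(self):
        t1 = parse_newick("((a,b),c);")
        t2 = parse_newick("((a,c),b);")
        assert semi_strict_consensus([t1, t2]) == parse_newick("(a,b,c);")

    def test_differing_tip_sets_rejected(self):
        with pytest.raises(TreeError):
            semi_strict_consensus([parse_newick("((a,b),c);"),
                                   parse_newick("((a,b),d);")])

    def test_multiset_equals_dedup_and_clades_compatible(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(10):
            trees = [random_topology(labels, rng) for _ in range(3)]
            cons = semi_strict_consensus(trees)
            assert cons == semi_strict_consensus(trees + trees)
            # every consensus clade is compatible with every input tree
            for c in cons.clades():
                for t in trees:
                    for d in t.clades():
                        inter = c & d
                        assert not inter or inter == c or inter == d


class TestResolutions:
    def test_binary_tree_is_its_own_resolution(self):
        t = parse_newick("((a,b),(c,d));")
        assert is_binary(t)
        assert resolve_polytomies(t) == [t]

    @pytest.mark.parametrize("nwk,count", [
        ("(a,b,c);", 3),
        ("(a,b,c,d);", 15),
        ("((a,b,c),(d,e,f));", 9),
    ])
    def test_resolution_counts(self, nwk, count):
        t = parse_newick(nwk)
        assert not is_binary(t)
        res = resolve_polytomies(t)
        assert len(res) == count
        assert all(r.is_binary() for r in res)
        assert len({r.canonical_key() for r in res}) == count

    def test_cap(self):
        t = parse_newick("(" + ",".join(f"x{i}" for i in range(10)) + ");")
        with pytest.raises(TreeError):
            resolve_polytomies(t, cap=100)


class TestRooting:
    def test_outgroup_monophyletic(self):
        t = parse_newick("(((a,b),(o1,o2)),c);")
        r = root_on_outgroup(t, ["o1", "o2"])
        # outgroup forms one side of the root
        sides = []
        for n in r.root.children:
            tips = set()
            stack = [n]
            while stack:
                x = stack.pop()
                if x.is_leaf:
                    tips.add(x.label)
                stack.extend(x.children)
            sides.append(tips)
        assert {"o1", "o2"} in sides

    def test_single_outgroup(self):
        t = parse_newick("((a,(b,c)),o);")
        r = root_on_outgroup(t, ["o"])
        assert r.tip_labels == {"a", "b", "c", "o"}


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 3), (4, 15), (5, 105)])
    def test_topology_counts(self, n, count):
        tops = enumerate_rooted_topologies([f"x{i}" for i in range(n)])
        assert len(tops) == count
        assert len({t.canonical_key() for t in tops}) == count


class TestGeneTreeSample:
    def test_mismatched_tips_rejected(self):
        with pytest.raises(TreeError):
            GeneTreeSample([parse_newick("((a,b),c);"),
                            parse_newick("((a,b),d);")])

    def test_lengths_stripped(self):
        s = GeneTreeSample([parse_newick("((a:1,b:2):1,c:4);",
                                         expect_branch_lengths=True)])
        assert all(n.length is None for n in s[0].postorder())


class TestParentalTree:
    def test_heights(self):
        tau = ParentalTree.from_newick("((A:1.0,B:1.0):1.5,C:2.5);")
        assert tau.root_height == pytest.approx(2.5)
        assert sorted(tau.durations()) == pytest.approx([1.0, 1.0, 1.5, 2.5])

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeError):
            ParentalTree.from_newick("((A:1.0,B:2.0):1.0,C:2.0);")
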