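import math

import numpy as np
import pytest
from scipy.linalg import expm

from hybcoal import coalprob as cp
from hybcoal.trees import (ParentalTree, TaxonMap, TreeError, parse_newick,
                           resolve_polytomies)

from conftest import random_topology


def three_taxon(T_internal=1.0, tmrca_offset=1.0):
    h = T_internal + tmrca_offset
    return ParentalTree.from_newick(
        f"((A:{tmrca_offset},B:{tmrca_offset}):{T_internal},C:{h});")


class TestTavare:
    def test_single_lineage(self):
        for T in (0.0, 0.5, 10.0, math.inf):
            assert cp.tavare_gij(1, 1, T) == pytest.approx(1.0)

    def test_pair_no_coalescence_closed_form(self):
        assert cp.tavare_gij(2, 2, 1.0) == pytest.approx(math.exp(-1), abs=1e-12)

    @pytest.mark.parametrize("i", range(2, 7))
    @pytest.mark.parametrize("T", [0.05, 0.5, 1.0, 5.0])
    def test_normalization(self, i, T):
        assert sum(cp.tavare_gij(i, j, T) for j in range(1, i + 1)) \
            == pytest.approx(1.0, abs=1e-12)

    def test_infinite_time(self):
        assert cp.tavare_gij(5, 1, math.inf) == 1.0
        assert cp.tavare_gij(5, 2, math.inf) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cp.tavare_gij(2, 3, 1.0)
        with pytest.raises(ValueError):
            cp.tavare_gij(2, 1, -0.1)

    @pytest.mark.parametrize("T", [1e-6, 0.01, 0.3, 2.0])
    def test_matches_matrix_exponential(self, T):
        """Independent oracle: the pure-death chain with rate C(k,2)."""
        n = 14
        Q = np.zeros((n + 1, n + 1))
        for k in range(2, n + 1):
            rate = k * (k - 1) / 2.0
            Q[k, k] = -rate
            Q[k, k - 1] = rate
        P = expm(Q * T)
        G = cp.gij_table(T, n)
        for i in range(1, n + 1):
            for j in range(1, i + 1):
                assert G[i, j] == pytest.approx(P[i, j], abs=1e-8)


class TestHistories:
    def test_concordant_three_taxon(self, tmap3):
        tau = three_taxon()
        g = parse_newick("((a,b),c);")
        assert len(cp.enumerate_histories(g, tau, tmap3)) == 2

    def test_discordant_three_taxon(self, tmap3):
        tau = three_taxon()
        g = parse_newick("((a,c),b);")
        assert len(cp.enumerate_histories(g, tau, tmap3)) == 1

    def test_single_species_two_individuals(self):
        tau = ParentalTree(parse_newick("A;"))
        tmap = TaxonMap({"a1": "A", "a2": "A"})
        g = parse_newick("(a1,a2);")
        assert len(cp.enumerate_histories(g, tau, tmap)) == 1

    def test_unmapped_species_rejected(self, tmap3):
        tau = ParentalTree.from_newick("(A:1,B:1);")
        with pytest.raises(TreeError):
            cp.enumerate_histories(parse_newick("((a,b),c);"), tau, tmap3)


class TestGeneTreeProb:
    @pytest.mark.parametrize("T", [0.05, 0.5, 1.0, 3.0])
    def test_three_taxon_closed_forms(self, tmap3, T):
        tau = three_taxon(T)
        conc = cp.gene_tree_prob(parse_newick("((a,b),c);"), tau, tmap3)
        disc = cp.gene_tree_prob(parse_newick("((a,c),b);"), tau, tmap3)
        assert conc == pytest.approx(1 - (2 / 3) * math.exp(-T), abs=1e-9)
        assert disc == pytest.approx((1 / 3) * math.exp(-T), abs=1e-9)

    def test_long_branch_limit(self, tmap3):
        tau = three_taxon(50.0)
        conc = cp.gene_tree_prob(parse_newick("((a,b),c);"), tau, tmap3)
        assert conc == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_internal_branch(self, tmap3):
        probs = [cp.gene_tree_prob(parse_newick("((a,b),c);"),
                                   three_taxon(T), tmap3)
                 for T in (0.1, 0.3, 0.8, 1.5, 3.0)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_matches_bruteforce_random_small(self):
        rng = np.random.default_rng(11)
        tau = ParentalTree.from_newick("((A:0.6,B:0.6):0.9,C:1.5);")
        tmap = TaxonMap({"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        for _ in range(8):
            g = random_topology(["a1", "a2", "b1", "c1"], rng)
            fast = cp.gene_tree_prob(g, tau, tmap)
            slow = cp.gene_tree_prob_bruteforce(g, tau, tmap)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_polytomy_marginalizes_resolutions(self):
        tau = ParentalTree.from_newick("(A:0.7,B:0.7);")
        tmap = TaxonMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        poly = parse_newick("((a1,a2,b1),b2);")
        direct = cp.gene_tree_prob(poly, tau, tmap)
        summed = sum(cp.gene_tree_prob(r, tau, tmap)
                     for r in resolve_polytomies(poly))
        assert direct == pytest.approx(summed, rel=1e-12)

    def test_exchangeable_individuals_symmetry(self):
        tau = ParentalTree.from_newick("(A:0.5,B:0.5);")
        tmap = TaxonMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        g1 = parse_newick("(((a1,b1),a2),b2);")
        g2 = parse_newick("(((a2,b2),a1),b1);")  # permute within species
        assert cp.gene_tree_prob(g1, tau, tmap) \
            == pytest.approx(cp.gene_tree_prob(g2, tau, tmap), rel=1e-12)


class TestAllTopologyProbs:
    @pytest.mark.parametrize("newick,mapping,n_topologies", [
        ("((A:1.0,B:1.0):1.0,C:2.0);",
         {"a": "A", "b": "B", "c": "C"}, 3),
        ("(A:0.7,B:0.7);",
         {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, 15),
        ("((A:0.4,B:0.4):0.8,C:1.2);",
         {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}, 105),
    ])
    def test_sums_to_one(self, newick, mapping, n_topologies):
        tau = ParentalTree.from_newick(newick)
        probs = cp.all_topology_probs(tau, TaxonMap(mapping))
        assert len(probs) == n_topologies
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_tip_cap(self):
        tau = ParentalTree.from_newick("(A:0.7,B:0.7);")
        tmap = TaxonMap({f"a{i}": "A" for i in range(5)}
                        | {f"b{i}": "B" for i in range(4)})
        with pytest.raises(TreeError):
            cp.all_topology_probs(tau, tmap, max_tips=7)

    def test_label_symmetry(self):
        """Exchangeable species under a symmetric tree give symmetric
        probabilities."""
        tau = ParentalTree.from_newick("(A:0.9,B:0.9);")
        tmap = TaxonMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        probs = cp.all_topology_probs(tau, tmap)
        swap = {"a1": "b1", "a2": "b2", "b1": "a1", "b2": "a2"}
        for key, p in probs.items():
            swapped = key
            for old, new in [("a1", "#1"), ("a2", "#2"), ("b1", "a1"),
                             ("b2", "a2"), ("#1", "b1"), ("#2", "b2")]:
                swapped = swapped.replace(old, new)
            q = probs[parse_newick(swapped).canonical_key()]
            assert p == pytest.approx(q, rel=1e-10)


class TestCachingContract:
    def test_branch_length_change_does_not_rebuild(self, tmap3):
        cp.clear_signature_cache()
        g = parse_newick("((a,b),c);")
        cp.gene_tree_prob(g, three_taxon(0.7), tmap3)
        builds = cp.signature_build_count()
        cp.gene_tree_prob(g, three_taxon(2.3), tmap3)  # same topologies
        assert cp.signature_build_count() == builds

    def test_new_topology_rebuilds(self, tmap3):
        cp.clear_signature_cache()
        cp.gene_tree_prob(parse_newick("((a,b),c);"), three_taxon(), tmap3)
        builds = cp.signature_build_count()
        cp.gene_tree_prob(parse_newick("((a,c),b);"), three_taxon(), tmap3)
        assert cp.signature_build_count() == builds + 1
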