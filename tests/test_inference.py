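import math

import numpy as np
import pytest

from hybcoal.model import (HybridizationModel, OptimizerConfig,
                           brent_minimize_1d, iterate_hybrid_assignments,
                           likelihood_ratio_test)
from hybcoal.simulate import (default_study_tree, draw_parental_assignments,
                              simulate_gene_trees, taxon_map_for)
from hybcoal.trees import GeneTreeSample, parse_newick


SAMPLES = {"H": 4, "P1": 4, "P2": 4, "O": 2}


def simulated_sample(gamma, n_loci, seed, samples=SAMPLES, t=(1.0, 1.0, 1.0)):
    """True (error-free) coalescent gene trees from the mixture."""
    S = default_study_tree(t)
    rng = np.random.default_rng(seed)
    k1 = draw_parental_assignments(n_loci, gamma, rng)
    tau1, tau2 = S.decompose(t)
    trees = (simulate_gene_trees(tau1, samples, k1,
                                 int(rng.integers(1, 2**31 - 1)))
             + simulate_gene_trees(tau2, samples, n_loci - k1,
                                   int(rng.integers(1, 2**31 - 1))))
    return S, taxon_map_for(samples), GeneTreeSample(trees)


def grid_search_best(model, n_gamma=21, n_t=11, t_upper=5.0):
    """Independent lattice-search oracle for the maximized log-likelihood."""
    gammas = np.linspace(0, 1, n_gamma)
    ts = np.linspace(1e-6, t_upper, n_t)
    best = -math.inf
    for t1 in ts:
        for t2 in ts:
            for t3 in ts:
                p1, p2 = model.component_probs((t1, t2, t3))
                for gam in gammas:
                    mix = gam * p1 + (1 - gam) * p2
                    if np.all(mix > 0):
                        ll = float(np.log(mix).sum())
                        if ll > best:
                            best = ll
    return best


class TestBrent:
    def test_quadratic(self):
        x, fx = brent_minimize_1d(lambda x: (x - 0.3) ** 2, 0.0, 1.0, 1e-6)
        assert x == pytest.approx(0.3, abs=1e-5)

    def test_monotone_returns_boundary_exactly(self):
        x, fx = brent_minimize_1d(lambda x: x, 0.0, 5.0, 1e-5)
        assert x == 0.0

    def test_cosine(self):
        # dense-grid oracle
        grid = np.linspace(0, 5, 100001)
        oracle = grid[np.argmin(np.cos(grid))]
        x, _ = brent_minimize_1d(math.cos, 0.0, 5.0, 1e-8)
        assert x == pytest.approx(oracle, abs=1e-4)
        assert x == pytest.approx(math.pi, abs=1e-6)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            brent_minimize_1d(lambda x: x, 1.0, 0.0, 1e-6)


class TestFit:
    def test_tau2_concordant_gives_gamma_zero(self, study_tree, study_map):
        conc = parse_newick(
            "(((((H_1,H_2),(H_3,H_4)),((P2_1,P2_2),(P2_3,P2_4))),"
            "((P1_1,P1_2),(P1_3,P1_4))),(O_1,O_2));")
        D = GeneTreeSample([conc] * 10)
        res = HybridizationModel(D, study_tree, study_map).fit()
        assert res.gamma_hat == pytest.approx(0.0, abs=1e-4)
        assert res.boundary_flags["gamma"]

    def test_tau1_concordant_gives_gamma_one(self, study_tree, study_map):
        conc = parse_newick(
            "(((((H_1,H_2),(H_3,H_4)),((P1_1,P1_2),(P1_3,P1_4))),"
            "((P2_1,P2_2),(P2_3,P2_4))),(O_1,O_2));")
        D = GeneTreeSample([conc] * 10)
        res = HybridizationModel(D, study_tree, study_map).fit()
        assert res.gamma_hat == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("seed", [101, 202])
    def test_beats_grid_oracle(self, seed):
        S, tmap, D = simulated_sample(0.5, 10, seed)
        model = HybridizationModel(D, S, tmap)
        res = model.fit()
        oracle = grid_search_best(model)
        assert res.llf >= oracle - 1e-3
        assert res.llf == pytest.approx(
            model.loglike(res.gamma_hat, res.t_hat), abs=1e-9)

    def test_determinism(self):
        S, tmap, D = simulated_sample(0.3, 10, 77)
        r1 = HybridizationModel(D, S, tmap).fit()
        r2 = HybridizationModel(D, S, tmap).fit()
        assert r1.gamma_hat == r2.gamma_hat
        assert r1.t_hat == r2.t_hat
        assert r1.llf == r2.llf

    def test_reported_within_bounds(self):
        S, tmap, D = simulated_sample(0.5, 10, 5)
        cfg = OptimizerConfig(t_upper=5.0)
        res = HybridizationModel(D, S, tmap, cfg).fit()
        assert 0.0 <= res.gamma_hat <= 1.0
        assert all(cfg.t_lower <= x <= cfg.t_upper for x in res.t_hat)


class TestLRT:
    def test_point_mass_at_zero(self, study_tree, study_map):
        conc = parse_newick(
            "(((((H_1,H_2),(H_3,H_4)),((P2_1,P2_2),(P2_3,P2_4))),"
            "((P1_1,P1_2),(P1_3,P1_4))),(O_1,O_2));")
        D = GeneTreeSample([conc] * 10)
        lrt = HybridizationModel(D, study_tree, study_map).test_no_hybridization()
        assert lrt.delta == pytest.approx(0.0, abs=1e-6)
        assert lrt.p_value == 1.0
        assert not lrt.reject_at(0.05)

    def test_half_chi2_reference(self):
        """p = 0.5 * P(chi2_1 >= delta); cross-checked against an
        independent chi-square survival implementation (erfc)."""
        from scipy import stats
        delta = 3.841459
        p_scipy = 0.5 * stats.chi2.sf(delta, 1)
        p_erfc = 0.5 * math.erfc(math.sqrt(delta / 2))
        assert p_scipy == pytest.approx(0.025, abs=1e-6)
        assert p_scipy == pytest.approx(p_erfc, rel=1e-12)

    @pytest.mark.parametrize("seed", [8, 21, 34])
    def test_nesting_invariant(self, seed):
        S, tmap, D = simulated_sample(0.4, 10, seed)
        lrt = likelihood_ratio_test(D, S, tmap)
        assert lrt.fit_full.llf >= lrt.fit_null.llf - 1e-6
        assert lrt.delta >= 0.0
        assert 0.0 < lrt.p_value <= 1.0


class TestIterate:
    def test_row_count_and_shared_tips(self):
        S, tmap, D = simulated_sample(0.5, 10, 13)
        table = iterate_hybrid_assignments(
            D, ["H", "P1", "P2"], "O", tmap)
        assert len(table) == 3
        assert sorted(table["hybrid"]) == ["H", "P1", "P2"]

    def test_true_assignment_usually_best(self):
        """The generating hybrid assignment attains the top log-likelihood
        in the majority of seeded replicates."""
        wins = 0
        n_rep = 11
        for seed in range(n_rep):
            S, tmap, D = simulated_sample(0.5, 10, 1000 + seed)
            table = iterate_hybrid_assignments(
                D, ["H", "P1", "P2"], "O", tmap)
            best = table.loc[table["lnL"].idxmax(), "hybrid"]
            wins += best == "H"
        assert wins > n_rep / 2

    def test_requires_three_ingroup(self):
        from hybcoal.trees import TreeError
        S, tmap, D = simulated_sample(0.5, 4, 2)
        with pytest.raises(TreeError):
            iterate_hybrid_assignments(D, ["H", "P1"], "O", tmap)
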