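"""Maximum-likelihood fitting of the hybridization mixture model.

The public surface follows the Model/Results idiom: build a
:class:`HybridizationModel` from a :class:`~hybcoal.trees.GeneTreeSample`,
a :class:`~hybcoal.hybridtree.HybridSpeciesTree` and a
:class:`~hybcoal.trees.TaxonMap`; ``fit()`` returns a
:class:`HybridizationResults` carrying the MLEs, the maximized
log-likelihood, boundary diagnostics and a ``summary()`` table, and
``test_no_hybridization()`` performs the likelihood-ratio test of
H0: gamma = 0.

Optimization is cyclic coordinate ascent with a bounded Brent-type
one-dimensional search, in the fixed order gamma, t1, t2, t3, repeated
until the log-likelihood and all parameters stabilize.  Because the null
hypothesis pins gamma to the boundary of its [0,1] range, the LRT statistic
is referred to a 50:50 mixture of a point mass at zero and chi-square with
one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coalprob import TopologySignature, gij_table, signature_for
from .hybridtree import HybridSpeciesTree, MixtureParams
from .trees import GeneTreeSample, TaxonMap, TreeError

__all__ = [
    "OptimizerConfig",
    "HybridizationModel",
    "HybridizationResults",
    "LRTResult",
    "brent_minimize_1d",
    "fit_hybrid_model",
    "likelihood_ratio_test",
    "iterate_hybrid_assignments",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the cyclic Brent search.

    ``t_upper`` bounds the interval estimates (the likelihood flattens as
    branch lengths grow, so an upper bound is required for the search to
    terminate); 5.0 coalescent units is the simulation-study default, 2.0
    a typical empirical choice.  Convergence requires both a relative
    log-likelihood change below ``rel_ll_tol`` and a maximum absolute
    parameter change below ``param_tol`` over a full cycle.
    """

    gamma_bounds: tuple[float, float] = (0.0, 1.0)
    t_upper: float = 5.0
    t_lower: float = 1e-6
    brent_tol: float = 1e-5
    max_cycles: int = 100
    rel_ll_tol: float = 1e-6
    param_tol: float = 1e-4
    boundary_tol: float = 1e-3

    def __post_init__(self):
        if not self.t_lower < self.t_upper:
            raise ValueError("require t_lower < t_upper")
        if min(self.brent_tol, self.rel_ll_tol, self.param_tol) <= 0:
            raise ValueError("tolerances must be positive")


def brent_minimize_1d(f: Callable[[float], float], lo: float, hi: float,
                      tol: float) -> tuple[float, float]:
    """Bounded one-dimensional minimization (Brent-type parabolic
    interpolation + golden section).  The endpoints are evaluated
    explicitly, so boundary minima are returned exactly as ``lo`` or
    ``hi``."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    best_x, best_f = float(res.x), float(res.fun)
    if not math.isfinite(best_f):
        raise ValueError("non-finite objective during 1-D optimization")
    # snap to an endpoint when it is at least as good; the bounded search
    # converges adjacent to a boundary minimum, so checking only nearby
    # endpoints preserves the exact-boundary contract
    for edge in (lo, hi):
        if abs(best_x - edge) < 50 * tol:
            fe = f(edge)
            if fe <= best_f:
                best_x, best_f = edge, fe
    return best_x, best_f


class _BatchedSignatures:
    """Signature tables of all loci for one parental-tree topology, stacked
    into flat arrays so one likelihood evaluation is a single vectorized
    pass."""

    def __init__(self, sigs: list[TopologySignature]):
        self.n_loci = len(sigs)
        self.coefs = np.concatenate([s.coefs for s in sigs])
        self.I = np.vstack([s.I for s in sigs])
        self.J = np.vstack([s.J for s in sigs])
        self.locus = np.repeat(np.arange(self.n_loci),
                               [len(s.coefs) for s in sigs])
        self.max_i = max(s.max_i for s in sigs)
        # per-branch gathered factors, keyed (branch, duration): coordinate
        # optimization changes only a few durations per evaluation
        self._vcache: dict[tuple[int, float], np.ndarray] = {}

    def probs(self, durations: np.ndarray,
              table_cache: dict[float, np.ndarray]) -> np.ndarray:
        P = self.coefs.copy()
        for b, T in enumerate(durations):
            T = float(T)
            V = self._vcache.get((b, T))
            if V is None:
                G = table_cache.get(T)
                if G is None:
                    G = gij_table(T, self.max_i)
                    table_cache[T] = G
                V = G[self.I[:, b], self.J[:, b]]
                if len(self._vcache) > 512:
                    self._vcache.clear()
                self._vcache[(b, T)] = V
            P *= V
        return np.bincount(self.locus, weights=P, minlength=self.n_loci)


class HybridizationModel:
    """Mixture model for hybridization in the presence of incomplete
    lineage sorting.

    Parameters
    ----------
    data :
        Multi-locus rooted gene-tree topologies (branch lengths ignored).
        Multifurcating trees (e.g. consensus of tied ML estimates) are
        allowed; their probability marginalizes over binary resolutions.
    species_tree :
        The fixed hybrid species tree designating H, P1, P2 and O.
    taxon_map :
        Individual-to-species assignment covering every tip label.
    config :
        Optimizer settings; defaults follow :class:`OptimizerConfig`.
    """

    def __init__(self, data: GeneTreeSample, species_tree: HybridSpeciesTree,
                 taxon_map: TaxonMap, config: OptimizerConfig | None = None):
        self.data = data
        self.species_tree = species_tree
        self.taxon_map = taxon_map
        self.config = config or OptimizerConfig()
        for tip in data.tip_labels:
            sp = taxon_map.species_of(tip)
            if sp not in species_tree.species:
                raise TreeError(f"tip {tip!r} maps to species {sp!r} not in "
                                "the hybrid species tree")
        # signature tables depend only on topologies; build once per locus
        tau1, tau2 = species_tree.decompose((1.0, 1.0, 1.0))
        self._sigs1: list[TopologySignature] = [
            signature_for(g, tau1, taxon_map) for g in data]
        self._sigs2: list[TopologySignature] = [
            signature_for(g, tau2, taxon_map) for g in data]
        self._batch1 = _BatchedSignatures(self._sigs1)
        self._batch2 = _BatchedSignatures(self._sigs2)
        self._table_cache: dict[float, np.ndarray] = {}

    @classmethod
    def from_files(cls, genetrees_path: str, map_path: str, species_path: str,
                   config: OptimizerConfig | None = None) -> "HybridizationModel":
        from .trees import load_taxon_map
        return cls(GeneTreeSample.from_file(genetrees_path),
                   HybridSpeciesTree.from_json(species_path),
                   load_taxon_map(map_path), config)

    # -- likelihood ----------------------------------------------------
    def component_probs(self, t: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus gene-tree probabilities under tau1 and tau2 at
        intervals ``t``."""
        tau1, tau2 = self.species_tree.decompose(tuple(t))
        d1, d2 = tau1.durations(), tau2.durations()
        cache = self._table_cache
        if len(cache) > 4096:
            cache.clear()
        p1 = self._batch1.probs(d1, cache)
        p2 = self._batch2.probs(d2, cache)
        return p1, p2

    def loglike(self, gamma: float, t: Sequence[float]) -> float:
        """Mixture log-likelihood at (gamma, t)."""
        p1, p2 = self.component_probs(t)
        return self._ll_from_components(gamma, p1, p2)

    @staticmethod
    def _ll_from_components(gamma: float, p1: np.ndarray, p2: np.ndarray) -> float:
        mix = gamma * p1 + (1.0 - gamma) * p2
        if np.any(mix <= 0.0):
            return -math.inf
        return float(np.log(mix).sum())

    def loglike_params(self, params: MixtureParams) -> float:
        return self.loglike(params.gamma, params.t)

    # -- fitting -------------------------------------------------------
    def fit(self, start: MixtureParams | None = None,
            fix_gamma: float | None = None) -> "HybridizationResults":
        """Cyclic coordinate maximization: gamma, then t1, t2, t3, repeated
        to convergence.  ``fix_gamma`` pins gamma (used by the null fit of
        the LRT)."""
        cfg = self.config
        if start is None:
            start = MixtureParams(0.5 if fix_gamma is None else fix_gamma,
                                  (1.0, 1.0, 1.0))
        gamma = float(start.gamma) if fix_gamma is None else float(fix_gamma)
        t = [min(max(x, cfg.t_lower), cfg.t_upper) for x in start.t]
        ll = self.loglike(gamma, t)
        if not math.isfinite(ll):
            raise TreeError("all-zero gene-tree probabilities at the "
                            "starting point; check the taxon map")
        converged = False
        cycles = 0
        for cycles in range(1, cfg.max_cycles + 1):
            ll_prev, gamma_prev, t_prev = ll, gamma, list(t)
            if fix_gamma is None:
                p1, p2 = self.component_probs(t)
                gamma, neg = brent_minimize_1d(
                    lambda g: -self._ll_from_components(g, p1, p2),
                    cfg.gamma_bounds[0], cfg.gamma_bounds[1], cfg.brent_tol)
                ll = -neg
            for k in range(3):
                def f(x: float, _k: int = k) -> float:
                    tt = list(t)
                    tt[_k] = x
                    return -self.loglike(gamma, tt)
                t[k], neg = brent_minimize_1d(f, cfg.t_lower, cfg.t_upper,
                                              cfg.brent_tol)
                ll = -neg
            dparam = max([abs(gamma - gamma_prev)]
                         + [abs(a - b) for a, b in zip(t, t_prev)])
            dll = abs(ll - ll_prev) / max(1.0, abs(ll))
            if dll < cfg.rel_ll_tol and dparam < cfg.param_tol:
                converged = True
                break
        params = MixtureParams(gamma, tuple(t))
        return HybridizationResults(self, params, ll, cycles, converged,
                                    gamma_fixed=fix_gamma is not None)

    # -- testing -------------------------------------------------------
    def test_no_hybridization(self, fit_full: "HybridizationResults | None" = None
                              ) -> "LRTResult":
        """Likelihood-ratio test of H0: gamma = 0 against the two-sided
        alternative, using the 50:50 chi2_1 / point-mass-at-0 null."""
        full = fit_full if fit_full is not None else self.fit()
        null = self.fit(start=MixtureParams(0.0, full.t_hat), fix_gamma=0.0)
        if full.llf < null.llf:
            # the cyclic search reached a worse local optimum in the larger
            # model; restart it from the null solution, which restores the
            # nesting guarantee (the first gamma step can only improve)
            refit = self.fit(start=MixtureParams(0.0, null.t_hat))
            if refit.llf > full.llf:
                full = refit
        delta = 2.0 * (full.llf - null.llf)
        if delta < -1e-8:
            raise TreeError(f"negative LRT statistic ({delta:.3g}): "
                            "optimizer failure in the unrestricted fit")
        delta = max(delta, 0.0)
        p = 1.0 if delta == 0.0 else 0.5 * float(stats.chi2.sf(delta, df=1))
        return LRTResult(delta=delta, p_value=p, fit_full=full, fit_null=null)


class HybridizationResults:
    """MLEs, maximized log-likelihood and diagnostics for a fitted
    hybridization model."""

    def __init__(self, model: HybridizationModel, params: MixtureParams,
                 llf: float, cycles_used: int, converged: bool,
                 gamma_fixed: bool = False):
        self.model = model
        self.params = params
        self.llf = llf
        self.cycles_used = cycles_used
        self.converged = converged
        self.gamma_fixed = gamma_fixed

    @property
    def gamma_hat(self) -> float:
        return self.params.gamma

    @property
    def t_hat(self) -> tuple[float, float, float]:
        return self.params.t

    @property
    def boundary_flags(self) -> dict[str, bool]:
        cfg = self.model.config
        tol = cfg.boundary_tol
        flags = {"gamma": min(abs(self.gamma_hat - cfg.gamma_bounds[0]),
                              abs(self.gamma_hat - cfg.gamma_bounds[1])) < tol}
        for k, x in enumerate(self.t_hat, 1):
            flags[f"t{k}"] = (abs(x - cfg.t_upper) < tol
                              or abs(x - cfg.t_lower) < tol)
        return flags

    def test_no_hybridization(self) -> "LRTResult":
        return self.model.test_no_hybridization(fit_full=self)

    def to_dict(self) -> dict:
        return {"gamma_hat": self.gamma_hat, "t_hat": list(self.t_hat),
                "lnL": self.llf, "cycles_used": self.cycles_used,
                "converged": self.converged,
                "boundary_flags": self.boundary_flags}

    def summary(self) -> str:
        S = self.model.species_tree
        cfg = self.model.config
        flags = self.boundary_flags
        lines = [
            "Hybridization mixture model (coalescent, topology-only)",
            "=" * 56,
            f"Hybrid: {S.hybrid}   Parents: {S.parent1}, {S.parent2}   "
            f"Outgroup: {S.outgroup}",
            f"Loci: {self.model.data.N}   Individuals: "
            f"{len(self.model.data.tip_labels)}",
            f"t bounds: [{cfg.t_lower:g}, {cfg.t_upper:g}] coalescent units",
            "-" * 56,
            f"{'param':>8} {'estimate':>12} {'at bound':>10}",
        ]
        rows = [("gamma", self.gamma_hat, flags["gamma"]),
                ("t1", self.t_hat[0], flags["t1"]),
                ("t2", self.t_hat[1], flags["t2"]),
                ("t3", self.t_hat[2], flags["t3"])]
        for name, val, fl in rows:
            lines.append(f"{name:>8} {val:>12.4f} {('yes' if fl else 'no'):>10}")
        lines += ["-" * 56,
                  f"ln L = {self.llf:.6f}   cycles = {self.cycles_used}   "
                  f"converged = {self.converged}"]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<HybridizationResults gamma={self.gamma_hat:.4f} "
                f"t={tuple(round(x, 4) for x in self.t_hat)} "
                f"lnL={self.llf:.4f}>")


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of no hybridization (gamma = 0)."""

    delta: float
    p_value: float
    fit_full: HybridizationResults
    fit_null: HybridizationResults

    def reject_at(self, alpha: float) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return {"delta": self.delta, "p_value": self.p_value,
                "full": self.fit_full.to_dict(),
                "null": self.fit_null.to_dict()}


# ---------------------------------------------------------------------------
# functional wrappers and ITERATE mode
# ---------------------------------------------------------------------------

def fit_hybrid_model(D: GeneTreeSample, S: HybridSpeciesTree, tmap: TaxonMap,
                     cfg: OptimizerConfig | None = None) -> HybridizationResults:
    return HybridizationModel(D, S, tmap, cfg).fit()


def likelihood_ratio_test(D: GeneTreeSample, S: HybridSpeciesTree,
                          tmap: TaxonMap,
                          cfg: OptimizerConfig | None = None) -> LRTResult:
    return HybridizationModel(D, S, tmap, cfg).test_no_hybridization()


def iterate_hybrid_assignments(D: GeneTreeSample, species: Sequence[str],
                               outgroup: str, tmap: TaxonMap,
                               cfg: OptimizerConfig | None = None
                               ) -> pd.DataFrame:
    """ITERATE mode: when the hybrid cannot be named a priori, fit the model
    once with each ingroup species cast as the hybrid of the remaining pair.

    Returns one row per assignment with the MLEs, log-likelihood, LRT
    statistic and p-value.  The parent1/parent2 roles are interchangeable
    (gamma and 1-gamma swap), so parents are ordered alphabetically.
    """
    ingroup = sorted(set(species) - {outgroup})
    if len(ingroup) < 3:
        raise TreeError("ITERATE requires at least 3 ingroup species")
    if len(ingroup) > 3:
        raise TreeError("only the 3-ingroup (4-taxon) design is supported")
    rows = []
    for hyb in ingroup:
        pa, pb = sorted(set(ingroup) - {hyb})
        S = HybridSpeciesTree(hyb, pa, pb, outgroup)
        lrt = HybridizationModel(D, S, tmap, cfg).test_no_hybridization()
        full = lrt.fit_full
        rows.append({"hybrid": hyb, "parent1": pa, "parent2": pb,
                     "gamma_hat": full.gamma_hat,
                     "t1_hat": full.t_hat[0], "t2_hat": full.t_hat[1],
                     "t3_hat": full.t_hat[2], "lnL": full.llf,
                     "delta": lrt.delta, "p_value": lrt.p_value})
    return pd.DataFrame(rows)
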