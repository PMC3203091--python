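"""Simulation pipeline: binomial locus assignment, multispecies-coalescent
gene trees, JC69 sequence evolution, gene-tree re-estimation, and the
power-study driver.

The study design mirrors a four-taxon hybrid species tree with intervals
t = (1, 1, 1) coalescent units, 4 sampled individuals in each ingroup
species and 2 in the outgroup (14 tips), 10 loci of 500 bp with per-locus
theta = 5.0, and coalescent branch lengths converted to substitutions/site
by a factor of 0.005 (= theta / sites / 2).  Gene trees are simulated with
msprime (an island model with no migration reduces to the standard
multispecies coalescent), sequences evolve under JC69, and each locus's
gene tree is re-estimated by maximum likelihood before fitting the mixture
model — so the study measures performance with realistic gene-tree
estimation error, not with true gene trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from .hybridtree import HybridSpeciesTree
from .mltree import Alignment, estimate_gene_tree
from .model import HybridizationModel, OptimizerConfig
from .trees import GeneTreeSample, Node, ParentalTree, TaxonMap, Tree

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "StudySummary",
    "default_study_tree",
    "taxon_map_for",
    "draw_parental_assignments",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "simulate_sequences_jc69",
    "run_power_study",
    "power_table",
]


def default_study_tree(t: tuple[float, float, float] = (1.0, 1.0, 1.0)
                       ) -> HybridSpeciesTree:
    """The four-taxon study tree: hybrid H of parents P1/P2, outgroup O."""
    return HybridSpeciesTree("H", "P1", "P2", "O", t)


def taxon_map_for(samples: dict[str, int]) -> TaxonMap:
    """Individuals named ``<species>_<k>``, k = 1..n per species."""
    return TaxonMap({f"{sp}_{k + 1}": sp
                     for sp, n in samples.items() for k in range(n)})


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one level of the true hybridization proportion.

    Defaults are the motivating empirical design: 10 loci, samples
    (4, 4, 4, 2) over (H, P1, P2, O), intervals (1, 1, 1) coalescent units,
    theta = 5.0 per locus, 500 bp under JC69 at branch scale 0.005,
    branch-length bound 5.0 and test level alpha = 0.05.
    """

    gamma: float = 0.0
    n_loci: int = 10
    samples: tuple[tuple[str, int], ...] = (("H", 4), ("P1", 4),
                                            ("P2", 4), ("O", 2))
    t: tuple[float, float, float] = (1.0, 1.0, 1.0)
    theta: float = 5.0
    seq_length: int = 500
    branch_scale: float = 0.005
    n_replicates: int = 100
    alpha: float = 0.05
    t_upper: float = 5.0
    seed: int = 1

    @property
    def samples_dict(self) -> dict[str, int]:
        return dict(self.samples)

    def species_tree(self) -> HybridSpeciesTree:
        return default_study_tree(self.t)


def draw_parental_assignments(n_loci: int, gamma_true: float,
                              rng: np.random.Generator) -> int:
    """Number of loci whose history follows tau1 ~ Binomial(n_loci, gamma);
    the rest follow tau2."""
    if not 0.0 <= gamma_true <= 1.0:
        raise ValueError("gamma must be in [0,1]")
    return int(rng.binomial(n_loci, gamma_true))


# ---------------------------------------------------------------------------
# coalescent gene trees (msprime)
# ---------------------------------------------------------------------------

def _demography(tau: ParentalTree) -> tuple[msprime.Demography, dict[int, str]]:
    dem = msprime.Demography()
    names: dict[int, str] = {}
    counter = [0]
    # declare tip populations first, then ancestral ones
    for node in tau.tree.postorder():
        if node.is_leaf:
            names[id(node)] = node.label
            dem.add_population(name=node.label, initial_size=1.0)
    for node in tau.tree.postorder():
        if not node.is_leaf:
            counter[0] += 1
            nm = f"anc{counter[0]}"
            names[id(node)] = nm
            dem.add_population(name=nm, initial_size=1.0)

    splits = []
    for node in tau.tree.postorder():
        if node.is_leaf:
            continue
        splits.append((tau.heights[id(node)],
                       [names[id(c)] for c in node.children],
                       names[id(node)]))
    for t, derived, anc in sorted(splits, key=lambda x: x[0]):
        dem.add_population_split(time=t, derived=derived, ancestral=anc)
    dem.sort_events()
    return dem, names


def simulate_gene_trees(tau: ParentalTree, samples: dict[str, int],
                        n: int, seed: int) -> list[Tree]:
    """Simulate ``n`` independent multispecies-coalescent gene trees on
    ``tau`` (time in coalescent units; branch lengths retained)."""
    if n == 0:
        return []
    total = sum(samples.values())
    if total == 1:
        sp = next(s for s, k in samples.items() if k == 1)
        return [Tree(Node(f"{sp}_1")) for _ in range(n)]
    dem, _ = _demography(tau)
    sample_sets = {sp: k for sp, k in samples.items() if k > 0}
    reps = msprime.sim_ancestry(samples=sample_sets, demography=dem,
                                ploidy=1, num_replicates=n,
                                random_seed=max(1, seed))
    out = []
    for ts in reps:
        labels = {}
        counts: dict[str, int] = {}
        for s in ts.samples():
            pop = ts.population(ts.node(s).population).metadata["name"]
            counts[pop] = counts.get(pop, 0) + 1
            labels[s] = f"{pop}_{counts[pop]}"
        tr = ts.first()

        def rec(u: int) -> Node:
            kids = tr.children(u)
            if not kids:
                return Node(labels[u])
            return Node(None, None, [rec(c) for c in kids])

        root = tr.root
        node = rec(root)
        # set branch lengths from node times
        def set_len(u: int, my: Node, parent_time: float | None):
            my.length = (None if parent_time is None
                         else parent_time - tr.time(u))
            for c, mc in zip(tr.children(u), my.children):
                set_len(c, mc, tr.time(u))
        set_len(root, node, None)
        out.append(Tree(node))
    return out


def simulate_gene_tree(tau: ParentalTree, samples: dict[str, int],
                       rng: np.random.Generator) -> Tree:
    """A single coalescent gene tree (convenience wrapper)."""
    seed = int(rng.integers(1, 2**31 - 1))
    return simulate_gene_trees(tau, samples, 1, seed)[0]


# ---------------------------------------------------------------------------
# JC69 sequence evolution
# ---------------------------------------------------------------------------

def simulate_sequences_jc69(gene_tree: Tree, seq_length: int,
                            branch_scale: float,
                            rng: np.random.Generator) -> Alignment:
    """Evolve i.i.d. sites down the tree under JC69.

    ``branch_scale`` converts coalescent-unit branch lengths into expected
    substitutions per site; the root state is uniform over ACGT.  Each site
    changes along a branch of scaled length d with probability
    (3/4)(1 - e^{-4d/3}), uniformly to one of the three other bases.
    """
    root_seq = rng.integers(0, 4, size=seq_length).astype(np.uint8)
    labels: list[str] = []
    rows: list[np.ndarray] = []

    def rec(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            labels.append(node.label)
            rows.append(seq)
            return
        for c in node.children:
            d = (c.length or 0.0) * branch_scale
            p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            child_seq = seq.copy()
            hit = rng.random(seq_length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # uniform among the three other bases
                child_seq[hit] = (child_seq[hit]
                                  + rng.integers(1, 4, size=n_hit)) % 4
            rec(c, child_seq.astype(np.uint8))

    rec(gene_tree.root, root_seq)
    order = np.argsort(labels)
    return Alignment([labels[i] for i in order],
                     np.array([rows[i] for i in order]))


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

@dataclass
class StudySummary:
    """Per-replicate results and Table-style aggregates for one true-gamma
    level."""

    config: SimulationConfig
    records: pd.DataFrame      # per successful replicate
    n_failures: int = 0

    @property
    def n_ok(self) -> int:
        return len(self.records)

    @property
    def mean_gamma(self) -> float:
        return float(self.records["gamma_hat"].mean())

    @property
    def power(self) -> float:
        return float(self.records["reject"].mean())

    def t_means(self, exclude_boundary: bool = False) -> tuple[float, float, float]:
        df = self.records
        out = []
        for k in (1, 2, 3):
            col = df[f"t{k}_hat"]
            if exclude_boundary:
                col = col[~df[f"t{k}_boundary"]]
            out.append(float(col.mean()) if len(col) else math.nan)
        return tuple(out)

    def boundary_counts(self) -> dict[str, int]:
        return {f"t{k}": int(self.records[f"t{k}_boundary"].sum())
                for k in (1, 2, 3)}

    def row(self) -> dict:
        """One row in the layout of the simulation-study results table."""
        df = self.records
        r = {"gamma_true": self.config.gamma,
             "n": self.n_ok,
             "mean_gamma_hat": self.mean_gamma,
             "sd_gamma_hat": float(df["gamma_hat"].std(ddof=1)) if self.n_ok > 1 else math.nan}
        excl = self.t_means(exclude_boundary=True)
        for k in (1, 2, 3):
            r[f"mean_t{k}_hat"] = float(df[f"t{k}_hat"].mean())
            r[f"sd_t{k}_hat"] = (float(df[f"t{k}_hat"].std(ddof=1))
                                 if self.n_ok > 1 else math.nan)
            # interval means excluding boundary-capped replicates, since
            # capped estimates understate the (infinite-supremum) MLE
            r[f"mean_t{k}_hat_interior"] = excl[k - 1]
        r["power"] = self.power
        for k, v in self.boundary_counts().items():
            r[f"boundary_{k}"] = v
        r["n_failures"] = self.n_failures
        return r


def _run_replicate(cfg: SimulationConfig, rep: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, rep]))
    S = cfg.species_tree()
    tmap = taxon_map_for(cfg.samples_dict)
    k1 = draw_parental_assignments(cfg.n_loci, cfg.gamma, rng)
    tau1, tau2 = S.decompose(cfg.t)
    seed1 = int(rng.integers(1, 2**31 - 1))
    seed2 = int(rng.integers(1, 2**31 - 1))
    sims = (simulate_gene_trees(tau1, cfg.samples_dict, k1, seed1)
            + simulate_gene_trees(tau2, cfg.samples_dict, cfg.n_loci - k1, seed2))
    estimated = []
    for tr in sims:
        aln = simulate_sequences_jc69(tr, cfg.seq_length, cfg.branch_scale, rng)
        estimated.append(estimate_gene_tree(aln, tmap, S.outgroup))
    D = GeneTreeSample(estimated)
    model = HybridizationModel(D, S, tmap,
                               OptimizerConfig(t_upper=cfg.t_upper))
    lrt = model.test_no_hybridization()
    full = lrt.fit_full
    flags = full.boundary_flags
    rec = {"replicate": rep, "n_tau1": k1,
           "gamma_hat": full.gamma_hat,
           "t1_hat": full.t_hat[0], "t2_hat": full.t_hat[1],
           "t3_hat": full.t_hat[2], "lnL": full.llf,
           "delta": lrt.delta, "p_value": lrt.p_value,
           "reject": lrt.reject_at(cfg.alpha),
           "t1_boundary": flags["t1"], "t2_boundary": flags["t2"],
           "t3_boundary": flags["t3"],
           "converged": full.converged}
    return rec


def run_power_study(cfg: SimulationConfig) -> StudySummary:
    """Full pipeline per replicate (assignment, coalescent gene trees, JC69
    sequences, ML gene-tree estimation, mixture fit, LRT), aggregated.
    Per-replicate failures are logged and counted, not silently dropped."""
    records = []
    failures = 0
    for rep in range(cfg.n_replicates):
        try:
            records.append(_run_replicate(cfg, rep))
        except Exception:
            logger.exception("replicate %d failed", rep)
            failures += 1
    cols = ["replicate", "n_tau1", "gamma_hat", "t1_hat", "t2_hat", "t3_hat",
            "lnL", "delta", "p_value", "reject",
            "t1_boundary", "t2_boundary", "t3_boundary", "converged"]
    df = pd.DataFrame(records, columns=cols)
    return StudySummary(cfg, df, failures)


def power_table(summaries: list[StudySummary]) -> pd.DataFrame:
    """Stack per-level summaries into one results table."""
    return pd.DataFrame([s.row() for s in summaries])
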