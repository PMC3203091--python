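"""Hybrid species trees and the hybridization/ILS mixture likelihood.

A *hybrid species tree* is a four-taxon species tree with one hybrid edge:
a designated hybrid species H whose genome is a mosaic of contributions
from two parental species P1 and P2, plus an outgroup O.  It decomposes
into two ordinary *parental trees*,

    tau1 = (((H,P1),P2),O)      tau2 = (((H,P2),P1),O)

sharing node heights h1 = t1 (the hybridization/first-speciation time),
h2 = t1 + t2 and h3 = t1 + t2 + t3, where the t_i are the waiting times
between successive speciation events in coalescent units.  Each gene traces
its history through tau1 with probability gamma (the hybridization
proportion) and through tau2 with probability 1 - gamma, independently
across loci; within a parental tree gene-tree topologies follow the
multispecies coalescent.  The per-locus mixture probability is

    P(g | gamma, t) = gamma * P(g | t, tau1) + (1 - gamma) * P(g | t, tau2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .coalprob import gene_tree_prob
from .trees import GeneTreeSample, Node, ParentalTree, TaxonMap, Tree, TreeError

__all__ = [
    "HybridSpeciesTree",
    "MixtureParams",
    "decompose",
    "per_gene_mixture_prob",
    "log_likelihood",
]


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the mixture model: hybridization proportion gamma in
    [0,1] and speciation intervals t = (t1, t2, t3) >= 0 (coalescent
    units)."""

    gamma: float
    t: tuple[float, float, float]

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if len(self.t) != 3 or any(x < 0 for x in self.t):
            raise ValueError(f"t must be three nonnegative intervals, got {self.t}")
        object.__setattr__(self, "t", tuple(float(x) for x in self.t))


class HybridSpeciesTree:
    """Four-taxon species tree with a designated hybrid.

    Parameters
    ----------
    hybrid, parent1, parent2, outgroup :
        Species labels; must be mutually distinct.  ``parent1`` is the
        parent joined first in ``tau1`` (the gamma component).
    t :
        Default intervals (t1, t2, t3) used when callers do not supply
        their own.
    """

    def __init__(self, hybrid: str, parent1: str, parent2: str, outgroup: str,
                 t: tuple[float, float, float] = (1.0, 1.0, 1.0)):
        labels = [hybrid, parent1, parent2, outgroup]
        if len(set(labels)) != 4:
            raise TreeError(f"hybrid/parents/outgroup must be distinct: {labels}")
        self.hybrid = hybrid
        self.parent1 = parent1
        self.parent2 = parent2
        self.outgroup = outgroup
        self.t = tuple(float(x) for x in t)
        if any(x < 0 for x in self.t):
            raise TreeError(f"negative interval in t={self.t}")

    @property
    def species(self) -> frozenset[str]:
        return frozenset((self.hybrid, self.parent1, self.parent2, self.outgroup))

    @property
    def ingroup(self) -> tuple[str, str, str]:
        return (self.hybrid, self.parent1, self.parent2)

    def swapped_parents(self) -> "HybridSpeciesTree":
        return HybridSpeciesTree(self.hybrid, self.parent2, self.parent1,
                                 self.outgroup, self.t)

    # -- decomposition -------------------------------------------------
    def decompose(self, t: tuple[float, float, float] | None = None
                  ) -> tuple[ParentalTree, ParentalTree]:
        """The two parental trees (((H,Pa),Pb),O) with shared heights
        (t1, t1+t2, t1+t2+t3)."""
        t1, t2, t3 = self.t if t is None else t
        if min(t1, t2, t3) < 0:
            raise TreeError("negative interval")

        def build(pa: str, pb: str) -> ParentalTree:
            h1, h2, h3 = t1, t1 + t2, t1 + t2 + t3
            hp = Node(None, h2 - h1, [Node(self.hybrid, h1), Node(pa, h1)])
            hpp = Node(None, h3 - h2, [hp, Node(pb, h2)])
            root = Node(None, None, [hpp, Node(self.outgroup, h3)])
            return ParentalTree(Tree(root))

        return build(self.parent1, self.parent2), build(self.parent2, self.parent1)

    # -- serialization -------------------------------------------------
    @classmethod
    def from_json(cls, source) -> "HybridSpeciesTree":
        """Read a species-tree spec: JSON object (or path to one) with keys
        ``hybrid``, ``parent1``, ``parent2``, ``outgroup``, optional
        ``newick`` (leaf-set consistency check) and optional ``t``."""
        if isinstance(source, (str, bytes)) :
            with open(source) as fh:
                obj = json.load(fh)
        else:
            obj = dict(source)
        tree = cls(obj["hybrid"], obj["parent1"], obj["parent2"],
                   obj["outgroup"], tuple(obj.get("t", (1.0, 1.0, 1.0))))
        if "newick" in obj:
            from .trees import parse_newick
            tips = parse_newick(obj["newick"]).tip_labels
            if tips != tree.species:
                raise TreeError(
                    f"newick leaf set {sorted(tips)} does not match the "
                    f"declared species {sorted(tree.species)}")
        return tree

    def to_json(self) -> dict:
        return {"hybrid": self.hybrid, "parent1": self.parent1,
                "parent2": self.parent2, "outgroup": self.outgroup,
                "t": list(self.t)}

    def __repr__(self) -> str:  # pragma: no cover
        return (f"HybridSpeciesTree(H={self.hybrid}, P1={self.parent1}, "
                f"P2={self.parent2}, O={self.outgroup}, t={self.t})")


def decompose(S: HybridSpeciesTree, t: tuple[float, float, float] | None = None):
    """Module-level alias for :meth:`HybridSpeciesTree.decompose`."""
    return S.decompose(t)


def per_gene_mixture_prob(g: Tree, params: MixtureParams,
                          S: HybridSpeciesTree, tmap: TaxonMap) -> float:
    """gamma * P(g|t,tau1) + (1-gamma) * P(g|t,tau2)."""
    tau1, tau2 = S.decompose(params.t)
    p1 = gene_tree_prob(g, tau1, tmap)
    p2 = gene_tree_prob(g, tau2, tmap)
    return params.gamma * p1 + (1.0 - params.gamma) * p2


def log_likelihood(params: MixtureParams, D: GeneTreeSample,
                   S: HybridSpeciesTree, tmap: TaxonMap) -> float:
    """Sum over loci of ln of the per-gene mixture probability; -inf if any
    gene has zero probability under both parental trees."""
    if D.N < 1:
        raise TreeError("empty gene-tree sample")
    total = 0.0
    for g in D:
        p = per_gene_mixture_prob(g, params, S, tmap)
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total
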