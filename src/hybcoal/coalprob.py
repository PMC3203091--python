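"""Probability of a rooted gene-tree topology under the multispecies
coalescent.

Each branch of a species tree is treated as an independent population in
which ``k`` lineages coalesce at rate ``C(k,2)`` per coalescent unit; the
root population has infinite duration, so all remaining lineages coalesce
there.  The probability of an observed gene-tree topology is a sum over
*coalescent histories* — assignments of each gene-tree coalescence to the
species-tree branch on which it occurs:

    P(g | tau) = sum_h prod_b  g_{i_b, j_b}(T_b) * w_b(h) / d_b

where ``g_ij(T)`` is Tavare's probability that ``i`` lineages reduce to
``j`` in time ``T``, ``d_b = prod_{k=j+1..i} C(k,2)`` counts all ordered
coalescence sequences, and ``w_b`` counts those consistent with the gene
tree.

Two implementations are provided:

* :func:`enumerate_histories` / :func:`gene_tree_prob_bruteforce` — explicit
  enumeration, for small problems and as an internal cross-check;
* :func:`gene_tree_prob` — a dynamic program over *ancestral configurations*
  (the sets of gene lineages entering each species-tree branch) that
  aggregates histories into per-branch lineage-count signatures.  The
  signature table depends only on the topologies and the taxon map, so it is
  cached and re-used when branch lengths change during optimization.  The DP
  also handles multifurcating gene trees: a polytomy leaves the order of its
  children's coalescences unconstrained, which marginalizes over all binary
  resolutions of the polytomy.
"""

from __future__ import annotations

import math

import numpy as np

from .trees import Node, ParentalTree, TaxonMap, Tree, TreeError
from .trees import enumerate_rooted_topologies

__all__ = [
    "tavare_gij",
    "gij_table",
    "enumerate_histories",
    "gene_tree_prob",
    "gene_tree_prob_bruteforce",
    "all_topology_probs",
    "TopologySignature",
    "signature_for",
    "signature_build_count",
    "clear_signature_cache",
]


# ---------------------------------------------------------------------------
# Tavare's g_ij(T)
# ---------------------------------------------------------------------------

_COEF_CACHE: dict[int, np.ndarray] = {}


def _tavare_coefs(max_i: int) -> np.ndarray:
    """Tensor A with  g_ij(T) = sum_k A[i,j,k] * exp(-k(k-1)T/2)."""
    if max_i in _COEF_CACHE:
        return _COEF_CACHE[max_i]
    n = max_i + 1
    A = np.zeros((n, n, n))
    for i in range(1, n):
        for j in range(1, i + 1):
            for k in range(j, i + 1):
                num = 1.0
                for y in range(k):
                    num *= (j + y) * (i - y) / (i + y)
                c = ((2 * k - 1) * (-1.0) ** (k - j) * num
                     / (math.factorial(j) * math.factorial(k - j) * (j + k - 1)))
                A[i, j, k] = c
    _COEF_CACHE[max_i] = A
    return A


def gij_table(T: float, max_i: int) -> np.ndarray:
    """Matrix G with G[i, j] = P(i lineages -> j lineages in time T)."""
    if T < 0:
        raise ValueError("negative time")
    A = _tavare_coefs(max_i)
    if math.isinf(T):
        G = np.zeros((max_i + 1, max_i + 1))
        G[1:, 1] = 1.0
        G[0, 0] = 1.0
        return G
    k = np.arange(max_i + 1)
    ev = np.exp(-k * (k - 1) / 2.0 * T)
    G = A @ ev
    np.clip(G, 0.0, 1.0, out=G)
    G[0, 0] = 1.0  # empty branch: no lineages, probability one
    return G


def tavare_gij(i: int, j: int, T: float) -> float:
    """Probability that ``i`` lineages entering a population leave ``j``
    lineages after time ``T`` (coalescent units)."""
    if not (1 <= j <= i):
        raise ValueError(f"require 1 <= j <= i, got i={i}, j={j}")
    if T < 0:
        raise ValueError("negative time")
    if math.isinf(T):
        return 1.0 if j == 1 else 0.0
    return float(gij_table(T, i)[i, j])


_D_TABLE: dict[tuple[int, int], float] = {}


def _d_coef(i: int, j: int) -> float:
    """Number of distinct ordered sequences of i-j coalescences among i
    lineages: prod_{k=j+1..i} C(k,2)."""
    out = _D_TABLE.get((i, j))
    if out is None:
        out = 1.0
        for k in range(j + 1, i + 1):
            out *= k * (k - 1) / 2.0
        _D_TABLE[(i, j)] = out
    return out


# ---------------------------------------------------------------------------
# shared setup: gene-tree lineage algebra on bitmasks
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Bitmask bookkeeping for a rooted gene tree (polytomies allowed)."""

    def __init__(self, g: Tree):
        self.tips = sorted(g.tip_labels_list())
        self.bit = {lab: 1 << i for i, lab in enumerate(self.tips)}
        self.full = (1 << len(self.tips)) - 1

        # postorder ids
        self.nodes: list[Node] = list(g.postorder())
        self.node_id = {id(n): k for k, n in enumerate(self.nodes)}
        self.clade = np.zeros(len(self.nodes), dtype=object)
        parent: dict[int, int] = {}
        for k, n in enumerate(self.nodes):
            for c in n.children:
                parent[self.node_id[id(c)]] = k
        self.parent = parent
        for k, n in enumerate(self.nodes):
            if n.is_leaf:
                self.clade[k] = self.bit[n.label]
            else:
                m = 0
                for c in n.children:
                    m |= self.clade[self.node_id[id(c)]]
                self.clade[k] = m
        self.root_id = len(self.nodes) - 1

        # representation of a "complete" lineage (a full clade of node u):
        # (parent node id, child-slot bit); the root clade is terminal (None)
        self._rep: dict[int, tuple[int, int] | None] = {}
        for k, n in enumerate(self.nodes):
            if k == self.root_id:
                self._rep[self.clade[k]] = None
                continue
            p = self.parent[k]
            slot = self.nodes[p].children.index(n)
            self._rep[self.clade[k]] = (p, 1 << slot)
        # full child-slot mask per internal node
        self.slots_full = {k: (1 << len(n.children)) - 1
                           for k, n in enumerate(self.nodes) if not n.is_leaf}
        self.children_ids = {k: [self.node_id[id(c)] for c in n.children]
                             for k, n in enumerate(self.nodes) if not n.is_leaf}

    def rep(self, mask: int):
        return self._rep[mask]

    def merge(self, x: int, y: int) -> int | None:
        """Merge two lineages if the coalescence is consistent with the gene
        tree; return the merged mask, else None."""
        rx, ry = self._rep[x], self._rep[y]
        if rx is None or ry is None or rx[0] != ry[0]:
            return None
        v = rx[0]
        slots = rx[1] | ry[1]
        m = x | y
        if m not in self._rep:
            # a complete clade mask is always pre-seeded, so this is a
            # partial union of node v's children
            self._rep[m] = (v, slots)
        return m


def _initial_lineages(gidx: _GeneIndex, tmap: TaxonMap, species: str) -> tuple[int, ...]:
    masks = []
    for ind in tmap.individuals_of(species):
        if ind in gidx.bit:
            masks.append(gidx.bit[ind])
    return tuple(sorted(masks))


def _check_inputs(g: Tree, tau: ParentalTree, tmap: TaxonMap) -> None:
    for lab in g.tip_labels:
        sp = tmap.species_of(lab)
        if sp not in tau.species:
            raise TreeError(f"individual {lab!r} maps to species {sp!r} "
                            f"absent from the species tree")


# ---------------------------------------------------------------------------
# configuration DP -> signature table
# ---------------------------------------------------------------------------

class TopologySignature:
    """Branch-length-free summary of all coalescent histories of one gene
    tree on one species-tree topology.

    ``prob(durations)`` evaluates  sum_s coef_s * prod_b G_{T_b}[i_sb, j_sb]
    where the (i, j) are per-branch entering/leaving lineage counts and the
    coefficients absorb the combinatorial w/d factors (root branch already
    folded in, since g_{i1}(inf) = 1).
    """

    def __init__(self, coefs: np.ndarray, I: np.ndarray, J: np.ndarray,
                 max_i: int):
        self.coefs = coefs          # (n_sig,)
        self.I = I                  # (n_sig, B)
        self.J = J                  # (n_sig, B)
        self.max_i = max_i

    @property
    def n_signatures(self) -> int:
        return len(self.coefs)

    def prob(self, durations: np.ndarray,
             table_cache: dict[float, np.ndarray] | None = None) -> float:
        P = self.coefs.copy()
        for b, T in enumerate(durations):
            if table_cache is not None and T in table_cache:
                G = table_cache[T]
            else:
                G = gij_table(T, self.max_i)
                if table_cache is not None:
                    table_cache[T] = G
            P *= G[self.I[:, b], self.J[:, b]]
        return float(P.sum())


_SIG_CACHE: dict[tuple, TopologySignature] = {}
_SIG_BUILDS = 0


def signature_build_count() -> int:
    """Instrumentation: number of DP signature constructions performed
    (cache misses)."""
    return _SIG_BUILDS


def clear_signature_cache() -> None:
    global _SIG_BUILDS
    _SIG_CACHE.clear()
    _SIG_BUILDS = 0


class _LineageWalk:
    """Globally memoized merge algebra over configurations (sets of
    lineages) of one gene tree: single merge steps, full within-branch
    transition tables with ordered-sequence counts, and counts of complete
    coalescence sequences (for the root branch)."""

    def __init__(self, gidx: _GeneIndex, max_configs: int = 500_000):
        self.gidx = gidx
        self.max_configs = max_configs
        self._step: dict[tuple[int, ...], list] = {}
        self._trans: dict[tuple[int, ...], list] = {}
        self._complete: dict[tuple[int, ...], float] = {}

    def step(self, cfg: tuple[int, ...]):
        """Single-merge successors with multiplicities.  Configurations are
        kept as sorted tuples of lineage bitmasks."""
        r = self._step.get(cfg)
        if r is None:
            if len(self._step) > self.max_configs:
                raise TreeError("configuration space too large; the gene "
                                "tree is too unresolved for exact "
                                "marginalization")
            merge = self.gidx.merge
            acc: dict[tuple[int, ...], int] = {}
            n = len(cfg)
            for a in range(n):
                xa = cfg[a]
                for b in range(a + 1, n):
                    merged = merge(xa, cfg[b])
                    if merged is None:
                        continue
                    rest = cfg[:a] + cfg[a + 1:b] + cfg[b + 1:]
                    ncfg = tuple(sorted(rest + (merged,)))
                    acc[ncfg] = acc.get(ncfg, 0) + 1
            r = list(acc.items())
            self._step[cfg] = r
        return r

    def transitions(self, cfg: tuple[int, ...]):
        """All (config_after, n_ordered_merge_sequences); the number of
        merges is |cfg| - |config_after|."""
        r = self._trans.get(cfg)
        if r is None:
            acc: dict[frozenset[int], float] = {cfg: 1.0}
            for c1, k in self.step(cfg):
                for c2, n in self.transitions(c1):
                    acc[c2] = acc.get(c2, 0.0) + k * n
            r = list(acc.items())
            self._trans[cfg] = r
        return r

    def completions(self, cfg: tuple[int, ...]) -> float:
        """Number of ordered merge sequences reducing cfg to one lineage."""
        if len(cfg) == 1:
            return 1.0
        r = self._complete.get(cfg)
        if r is None:
            r = 0.0
            for c1, k in self.step(cfg):
                r += k * self.completions(c1)
            self._complete[cfg] = r
        return r


def _build_signature(g: Tree, tau: ParentalTree, tmap: TaxonMap) -> TopologySignature:
    gidx = _GeneIndex(g)
    walk = _LineageWalk(gidx)
    # per-branch (i, j) pairs are packed as a single int i*32+j; states are
    # kept config-major so transition tables and completion counts are
    # fetched once per distinct configuration

    def process(node: Node) -> dict[tuple, dict[tuple, float]]:
        """Return {config_at_top_of_node's_branch: {sig_prefix: coef}}."""
        if node.is_leaf:
            states = {_initial_lineages(gidx, tmap, node.label): {(): 1.0}}
        else:
            states = None
            for child in node.children:
                child_states = process(child)
                if states is None:
                    states = child_states
                    continue
                merged: dict[tuple, dict[tuple, float]] = {}
                for c1, sigs1 in states.items():
                    for c2, sigs2 in child_states.items():
                        u = tuple(sorted(c1 + c2))
                        tgt = merged.setdefault(u, {})
                        for s1, w1 in sigs1.items():
                            for s2, w2 in sigs2.items():
                                key = s1 + s2
                                tgt[key] = tgt.get(key, 0.0) + w1 * w2
                states = merged
        if node is tau.tree.root:
            return states
        # apply the branch above this node
        out: dict[tuple, dict[tuple, float]] = {}
        for cfg, sigs in states.items():
            i = len(cfg)
            if i == 0:
                enc = 0
                tgt = out.setdefault(cfg, {})
                for s, w in sigs.items():
                    key = s + (enc,)
                    tgt[key] = tgt.get(key, 0.0) + w
                continue
            for ncfg, cnt in walk.transitions(cfg):
                j = len(ncfg)
                f = cnt / _d_coef(i, j)
                enc = i * 32 + j
                tgt = out.setdefault(ncfg, {})
                for s, w in sigs.items():
                    key = s + (enc,)
                    tgt[key] = tgt.get(key, 0.0) + w * f
        return out

    states = process(tau.tree.root)
    # root branch (infinite duration): everything coalesces to one lineage;
    # g_{i,1}(inf) = 1, so only the sequence-count ratio enters
    final: dict[tuple, float] = {}
    for cfg, sigs in states.items():
        i = len(cfg)
        if i == 0:
            continue
        n_seq = walk.completions(cfg)
        if n_seq > 0.0:
            f = n_seq / _d_coef(i, 1)
            for s, w in sigs.items():
                final[s] = final.get(s, 0.0) + w * f

    B = len(tau.branch_nodes)
    n_tips = len(gidx.tips)
    sigs = sorted(final)
    coefs = np.array([final[s] for s in sigs])
    enc = np.array(sigs, dtype=np.int64).reshape(len(sigs), B)
    I = enc // 32
    J = enc % 32
    return TopologySignature(coefs, I, J, max(n_tips, 1))


def _species_canonical(g: Tree, tmap: TaxonMap) -> tuple[Tree, TaxonMap]:
    """Relabel individuals to a canonical per-species numbering.

    Individuals of the same species are exchangeable lineages under the
    coalescent, so P(g | tau) is invariant under permuting same-species tip
    labels.  Mapping every gene tree to a canonical representative makes the
    signature cache shared across such permutations (and across datasets
    that differ only in individual naming)."""
    counters: dict[str, int] = {}
    relabel: dict[str, str] = {}

    def key(n: Node) -> str:
        if n.is_leaf:
            return tmap.species_of(n.label)
        return "(" + ",".join(sorted(key(c) for c in n.children)) + ")"

    def rec(n: Node) -> Node:
        if n.is_leaf:
            sp = tmap.species_of(n.label)
            counters[sp] = counters.get(sp, 0) + 1
            new = f"{sp}#{counters[sp]}"
            relabel[new] = sp
            return Node(new)
        kids = sorted(n.children, key=key)
        return Node(None, None, [rec(c) for c in kids])

    return Tree(rec(g.root)), TaxonMap(relabel)


def signature_for(g: Tree, tau: ParentalTree, tmap: TaxonMap) -> TopologySignature:
    """Cached signature table for (gene-tree topology, species-tree topology,
    taxon map).  The cache key is the species-level canonical form of the
    gene tree (same-species individuals are exchangeable)."""
    global _SIG_BUILDS
    _check_inputs(g, tau, tmap)
    gc, mc = _species_canonical(g, tmap)
    key = (gc.canonical_key(), tau.topology_key(), mc.canonical_key())
    sig = _SIG_CACHE.get(key)
    if sig is None:
        _SIG_BUILDS += 1
        sig = _build_signature(gc, tau, mc)
        _SIG_CACHE[key] = sig
    return sig


def gene_tree_prob(g: Tree, tau: ParentalTree, tmap: TaxonMap) -> float:
    """P(gene-tree topology | species tree) under the multispecies
    coalescent, with any number of individuals per species.

    Multifurcating gene trees are allowed; the result is then the summed
    probability of all binary resolutions of the polytomies.
    """
    sig = signature_for(g, tau, tmap)
    return sig.prob(tau.durations())


def all_topology_probs(tau: ParentalTree, tmap: TaxonMap,
                       max_tips: int = 7) -> dict[str, float]:
    """Probabilities of every rooted binary labeled topology on the sampled
    individuals (keyed by canonical newick).  Sums to 1."""
    inds = sorted(tmap.individuals)
    if len(inds) > max_tips:
        raise TreeError(f"{len(inds)} individuals exceeds max_tips={max_tips}")
    out = {}
    for t in enumerate_rooted_topologies(inds):
        out[t.canonical_key()] = gene_tree_prob(t, tau, tmap)
    return out


# ---------------------------------------------------------------------------
# explicit history enumeration (oracle path; binary gene trees)
# ---------------------------------------------------------------------------

def _species_branch_index(tau: ParentalTree):
    """Map species-tree nodes to branch ids; the root branch gets id B."""
    ids = {id(n): k for k, n in enumerate(tau.branch_nodes)}
    ids[id(tau.tree.root)] = len(tau.branch_nodes)
    return ids


def _tau_ancestry(tau: ParentalTree):
    """parent branch id per branch id; species clade per branch id."""
    bid = _species_branch_index(tau)
    parent = {}
    clade = {}
    for n in tau.tree.postorder():
        k = bid[id(n)]
        cl = set()
        stack = [n]
        while stack:
            x = stack.pop()
            if x.is_leaf:
                cl.add(x.label)
            stack.extend(x.children)
        clade[k] = frozenset(cl)
        for c in n.children:
            parent[bid[id(c)]] = k
    return bid, parent, clade


def enumerate_histories(g: Tree, tau: ParentalTree, tmap: TaxonMap
                        ) -> list[dict[int, int]]:
    """All valid coalescent histories of a binary gene tree: maps from
    gene-tree internal-node postorder id to species-tree branch id (the root
    branch has the largest id).  Deterministic order."""
    if not g.is_binary():
        raise TreeError("history enumeration requires a binary gene tree")
    _check_inputs(g, tau, tmap)
    gidx = _GeneIndex(g)
    bid, bparent, bclade = _tau_ancestry(tau)
    root_bid = len(tau.branch_nodes)

    def ancestors(b: int) -> list[int]:
        out = [b]
        while b in bparent:
            b = bparent[b]
            out.append(b)
        return out

    # minimal branch per gene internal node: the population above the species
    # MRCA of its descendant individuals' species
    internal = [k for k, n in enumerate(gidx.nodes) if not n.is_leaf]
    min_branch = {}
    for k in internal:
        mask = gidx.clade[k]
        sps = {tmap.species_of(t) for t in gidx.tips
               if gidx.bit[t] & mask}
        b = 0
        for cand in range(root_bid + 1):
            if sps <= bclade[cand]:
                # smallest clade containing sps, searching postorder works
                # because postorder lists descendants before ancestors
                b = cand
                break
        else:  # pragma: no cover
            b = root_bid
        min_branch[k] = b

    # depth of each branch for ancestry comparisons
    anc_sets = {b: set(ancestors(b)) for b in range(root_bid + 1)}

    histories: list[dict[int, int]] = []
    assign: dict[int, int] = {}

    def rec(idx: int) -> None:
        if idx == len(internal):
            histories.append(dict(assign))
            return
        k = internal[idx]
        for b in ancestors(min_branch[k]):
            # b must be ancestral-or-equal to every internal child's branch
            ok = all(b in anc_sets[assign[c]]
                     for c in gidx.children_ids[k]
                     if not gidx.nodes[c].is_leaf)
            if ok:
                assign[k] = b
                rec(idx + 1)
                del assign[k]

    rec(0)
    return histories


def _linear_extensions(nodes: set[int], gidx: _GeneIndex) -> float:
    """Number of orderings of the given gene nodes consistent with the gene
    tree (children before parents): m! / prod(hook sizes)."""
    m = len(nodes)
    if m <= 1:
        return 1.0
    out = float(math.factorial(m))
    for k in nodes:
        # descendants of k within the set, including k
        desc = 1
        stack = list(gidx.children_ids.get(k, []))
        while stack:
            x = stack.pop()
            if x in nodes:
                desc += 1
            stack.extend(gidx.children_ids.get(x, []))
        out /= desc
    return out


def gene_tree_prob_bruteforce(g: Tree, tau: ParentalTree, tmap: TaxonMap) -> float:
    """P(g | tau) by explicit summation over enumerated histories.  Oracle
    for :func:`gene_tree_prob` on small problems."""
    gidx = _GeneIndex(g)
    bid, bparent, bclade = _tau_ancestry(tau)
    root_bid = len(tau.branch_nodes)
    durations = list(tau.durations()) + [math.inf]

    # sampled individuals whose species lies in the branch's clade
    tip_count = {b: sum(1 for t in gidx.tips if tmap.species_of(t) in bclade[b])
                 for b in range(root_bid + 1)}

    # strict descendants of each branch
    desc = {b: [] for b in range(root_bid + 1)}
    for b in range(root_bid + 1):
        p = b
        while p in bparent:
            p = bparent[p]
            desc[p].append(b)

    total = 0.0
    for h in enumerate_histories(g, tau, tmap):
        per_branch: dict[int, set[int]] = {}
        for node, b in h.items():
            per_branch.setdefault(b, set()).add(node)
        term = 1.0
        for b in range(root_bid + 1):
            assigned_below = sum(len(per_branch.get(d, ()))
                                 for d in desc[b])
            i = tip_count[b] - assigned_below
            S = per_branch.get(b, set())
            j = i - len(S)
            if i == 0:
                continue
            if b == root_bid:
                gfac = 1.0 if j == 1 else 0.0
            else:
                gfac = tavare_gij(i, j, durations[b])
            term *= gfac * _linear_extensions(S, gidx) / _d_coef(i, j)
        total += term
    return total
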