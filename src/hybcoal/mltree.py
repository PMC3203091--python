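"""Maximum-likelihood gene-tree estimation under JC69.

The primary estimator (:func:`estimate_gene_tree`) assumes a molecular
clock: rooted ultrametric trees parameterized by node heights
(substitutions/site), optimized by coordinate ascent from a UPGMA start
with rooted-NNI hill climbing.  Because coalescent gene trees are
ultrametric in time, the clock is the generating model for this package's
simulations, and it determines the root without an outgroup heuristic.
When two or more topologies tie for the ML score (within ``tie_tol``
log-units — common at short alignments where internal branches carry no
substitutions), the semi-strict consensus of the tied topologies is
returned, which may contain polytomies.

A clock-free unrooted searcher (:func:`ml_search`) is also provided: NJ on
JC-corrected distances plus NNI with per-edge branch-length optimization.
Under JC69 the transition matrix is P(d) = 1/4 + e^{-4d/3}(I - 1/4), so
every per-edge likelihood is *linear* in x = e^{-4d/3}; unrooted edge
optimization reduces to a concave 1-D problem in x solved by bisection on
the score derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import (Node, TaxonMap, Tree, TreeError,
                    semi_strict_consensus)

__all__ = ["Alignment", "jc69_distance_matrix", "estimate_gene_tree",
           "ml_search", "clock_ml_search"]

_XMIN = math.exp(-4.0)  # edge lengths capped at 3 substitutions/site
_DMAX = 3.0


@dataclass
class Alignment:
    """A multiple sequence alignment with bases encoded 0..3 (ACGT)."""

    labels: list[str]
    data: np.ndarray  # (n_seqs, n_sites) uint8

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("alignment shape does not match labels")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence_str(self, i: int) -> str:
        return "".join("ACGT"[b] for b in self.data[i])

    def to_fasta(self, path: str) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord
        recs = [SeqRecord(Seq(self.sequence_str(i)), id=lab, description="")
                for i, lab in enumerate(self.labels)]
        seqio_write(recs, path, "fasta")

    def to_phylip(self, path: str) -> None:
        """Relaxed PHYLIP (name, whitespace, sequence on one line)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)} {self.n_sites}\n")
            width = max(len(l) for l in self.labels) + 2
            for i, lab in enumerate(self.labels):
                fh.write(f"{lab:<{width}}{self.sequence_str(i)}\n")

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        from Bio import SeqIO
        labels, rows = [], []
        lut = {c: i for i, c in enumerate("ACGT")}
        for rec in SeqIO.parse(path, "fasta"):
            labels.append(rec.id)
            rows.append([lut[c] for c in str(rec.seq).upper()])
        return cls(labels, np.array(rows, dtype=np.uint8))


def jc69_distance_matrix(aln: Alignment) -> np.ndarray:
    """JC-corrected pairwise distances; saturated pairs capped at
    ``_DMAX``."""
    X = aln.data
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = (X[i] != X[i + 1:]).mean(axis=1)
        arg = 1.0 - 4.0 * diff / 3.0
        with np.errstate(invalid="ignore"):
            d = np.where(arg > math.exp(-4.0 * _DMAX / 3.0),
                         -0.75 * np.log(np.maximum(arg, 1e-12)), _DMAX)
        D[i, i + 1:] = D[i + 1:, i] = d
    return D


# ---------------------------------------------------------------------------
# unrooted tree with pruning machinery
# ---------------------------------------------------------------------------

class _UTree:
    """Unrooted binary tree over ``n`` tips; nodes 0..n-1 are tips."""

    def __init__(self, n_tips: int, labels: list[str],
                 patterns: np.ndarray, weights: np.ndarray):
        self.n = n_tips
        self.labels = labels
        self.adj: dict[int, list[int]] = {}
        self.length: dict[tuple[int, int], float] = {}
        self.patterns = patterns      # (P, n_tips) uint8
        self.w = weights.astype(float)
        self._tipcond = {}
        P = patterns.shape[0]
        for i in range(n_tips):
            f = np.zeros((P, 4))
            f[np.arange(P), patterns[:, i]] = 1.0
            self._tipcond[i] = f

    # -- structure -----------------------------------------------------
    def _ekey(self, a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def add_edge(self, a: int, b: int, d: float) -> None:
        self.adj.setdefault(a, []).append(b)
        self.adj.setdefault(b, []).append(a)
        self.length[self._ekey(a, b)] = max(d, 1e-8)

    def remove_edge(self, a: int, b: int) -> None:
        self.adj[a].remove(b)
        self.adj[b].remove(a)
        del self.length[self._ekey(a, b)]

    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.length)

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.edges()
                if a >= self.n and b >= self.n]

    def d(self, a: int, b: int) -> float:
        return self.length[self._ekey(a, b)]

    # -- pruning -------------------------------------------------------
    def _evolve(self, f: np.ndarray, d: float) -> np.ndarray:
        x = math.exp(-4.0 * d / 3.0)
        return x * f + (1.0 - x) * 0.25 * f.sum(axis=1, keepdims=True)

    def messages(self) -> dict[tuple[int, int], np.ndarray]:
        """m[(x,y)] = conditional likelihood at x of the component holding x
        when edge (x,y) is cut."""
        m: dict[tuple[int, int], np.ndarray] = {}
        # iterative: process directed edges once all inputs are ready
        pending = [(x, y) for x in self.adj for y in self.adj[x]]
        while pending:
            rest = []
            for x, y in pending:
                if x < self.n:
                    m[(x, y)] = self._tipcond[x]
                    continue
                deps = [c for c in self.adj[x] if c != y]
                if all((c, x) in m for c in deps):
                    prod = None
                    for c in deps:
                        g = self._evolve(m[(c, x)], self.d(c, x))
                        prod = g if prod is None else prod * g
                    m[(x, y)] = prod
                else:
                    rest.append((x, y))
            pending = rest
        return m

    def loglike_edge(self, fu: np.ndarray, fv: np.ndarray, d: float) -> float:
        L = 0.25 * (fu * self._evolve(fv, d)).sum(axis=1)
        return float(self.w @ np.log(np.maximum(L, 1e-300)))

    def loglike(self, m: dict | None = None) -> float:
        u, v = self.edges()[0]
        m = m or self.messages()
        return self.loglike_edge(m[(u, v)], m[(v, u)], self.d(u, v))

    # -- per-edge optimization ----------------------------------------
    def _opt_x(self, fu: np.ndarray, fv: np.ndarray) -> tuple[float, float]:
        """Maximize the score over x = e^{-4d/3}; returns (x*, lnL*)."""
        Dp = (fu * fv).sum(axis=1)
        Sp = fu.sum(axis=1) * fv.sum(axis=1)
        alpha = Sp / 4.0
        beta = Dp - alpha
        # score'(x) = sum w*beta/(alpha+beta*x), monotone decreasing
        def deriv(x):
            return float((self.w * beta / np.maximum(alpha + beta * x, 1e-300)).sum())
        lo, hi = _XMIN, 1.0
        if deriv(hi) >= 0.0:
            x = hi
        elif deriv(lo) <= 0.0:
            x = lo
        else:
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if deriv(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            x = 0.5 * (lo + hi)
        ll = float(self.w @ np.log(np.maximum(0.25 * (alpha + beta * x), 1e-300)))
        return x, ll

    def optimize_lengths(self, n_sweeps: int = 2) -> float:
        """Top-down sweeps: one up-pass of messages, then optimize each edge
        in pre-order while propagating down-messages incrementally."""
        ll = -math.inf
        for _ in range(n_sweeps):
            root = self.n  # arbitrary internal node
            parent = {root: None}
            order = [root]
            stack = [root]
            while stack:
                x = stack.pop()
                for c in self.adj[x]:
                    if c != parent[x]:
                        parent[c] = x
                        order.append(c)
                        stack.append(c)
            # up-messages (toward root)
            up: dict[int, np.ndarray] = {}
            for x in reversed(order):
                if x == root:
                    continue
                if x < self.n:
                    up[x] = self._tipcond[x]
                else:
                    prod = None
                    for c in self.adj[x]:
                        if c == parent[x]:
                            continue
                        g = self._evolve(up[c], self.d(c, x))
                        prod = g if prod is None else prod * g
                    up[x] = prod
            # down-pass with per-edge optimization
            down: dict[int, np.ndarray] = {}
            for x in order:
                kids = [c for c in self.adj[x] if c != parent[x]]
                for c in kids:
                    prod = None
                    for s in self.adj[x]:
                        if s == c:
                            continue
                        f = down[x] if s == parent[x] else \
                            self._evolve(up[s], self.d(s, x))
                        prod = f if prod is None else prod * f
                    down_c = prod  # conditional at x of everything but c-side
                    xstar, ll = self._opt_x(up[c], down_c)
                    self.length[self._ekey(x, c)] = -0.75 * math.log(xstar)
                    down[c] = self._evolve(down_c, self.d(x, c))
        return ll

    # -- NNI -----------------------------------------------------------
    def nni_scores(self, m: dict, u: int, v: int):
        """Score the current and the two NNI arrangements around internal
        edge (u,v), optimizing only the central edge length.  Returns
        [(lnL, which)] for which in 0 (current), 1, 2."""
        a, b = [x for x in self.adj[u] if x != v]
        c, dd = [x for x in self.adj[v] if x != u]
        ea = self._evolve(m[(a, u)], self.d(a, u))
        eb = self._evolve(m[(b, u)], self.d(b, u))
        ec = self._evolve(m[(c, v)], self.d(c, v))
        ed = self._evolve(m[(dd, v)], self.d(dd, v))
        out = []
        for which, (fu, fv) in enumerate(
                [(ea * eb, ec * ed), (ea * ec, eb * ed), (ea * ed, eb * ec)]):
            x, ll = self._opt_x(fu, fv)
            out.append((ll, which, -0.75 * math.log(x)))
        return out, (a, b, c, dd)

    def apply_nni(self, u: int, v: int, which: int, central_d: float) -> None:
        a, b = [x for x in self.adj[u] if x != v]
        c, dd = [x for x in self.adj[v] if x != u]
        if which == 1:      # (a,c | b,d): swap b <-> c
            db, dc = self.d(b, u), self.d(c, v)
            self.remove_edge(b, u)
            self.remove_edge(c, v)
            self.add_edge(c, u, dc)
            self.add_edge(b, v, db)
        elif which == 2:    # (a,d | b,c): swap b <-> d
            db, dd_len = self.d(b, u), self.d(dd, v)
            self.remove_edge(b, u)
            self.remove_edge(dd, v)
            self.add_edge(dd, u, dd_len)
            self.add_edge(b, v, db)
        self.length[self._ekey(u, v)] = max(central_d, 1e-8)

    # -- export --------------------------------------------------------
    def to_rooted_tree(self) -> Tree:
        """Arbitrarily rooted topology-only Tree (for outgroup rooting)."""
        start = self.n
        def rec(x: int, parent: int | None) -> Node:
            if x < self.n:
                return Node(self.labels[x])
            return Node(None, None,
                        [rec(c, x) for c in self.adj[x] if c != parent])
        return Tree(rec(start, None))

    def copy(self) -> "_UTree":
        t = _UTree.__new__(_UTree)
        t.n, t.labels = self.n, self.labels
        t.patterns, t.w, t._tipcond = self.patterns, self.w, self._tipcond
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t.length = dict(self.length)
        return t


# ---------------------------------------------------------------------------
# NJ start
# ---------------------------------------------------------------------------

def _nj_start(aln: Alignment, patterns: np.ndarray, weights: np.ndarray) -> _UTree:
    import skbio
    from skbio.tree import nj

    n = len(aln.labels)
    if n < 3:
        raise TreeError("need at least 3 sequences")
    D = jc69_distance_matrix(aln)
    # skbio requires a hollow, symmetric matrix with unique ids
    ids = [str(i) for i in range(n)]
    snj = nj(skbio.DistanceMatrix(D, ids))
    tree = _UTree(n, aln.labels, patterns, weights)
    next_id = [n]
    index: dict[int, int] = {}

    def node_index(skn) -> int:
        key = id(skn)
        if key not in index:
            if skn.is_tip():
                index[key] = int(skn.name)
            else:
                index[key] = next_id[0]
                next_id[0] += 1
        return index[key]

    root = snj.root()
    for skn in snj.traverse(include_self=True):
        if skn is root:
            continue
        a = node_index(skn.parent)
        b = node_index(skn)
        d = skn.length if skn.length is not None else 0.0
        tree.add_edge(a, b, min(max(d, 1e-8), _DMAX))
    # suppress a degree-2 root if skbio produced one
    r = node_index(root)
    if len(tree.adj.get(r, [])) == 2:
        x, y = tree.adj[r]
        d = tree.d(x, r) + tree.d(y, r)
        tree.remove_edge(x, r)
        tree.remove_edge(y, r)
        tree.add_edge(x, y, d)
        del tree.adj[r]
    return tree


# ---------------------------------------------------------------------------
# search driver
# ---------------------------------------------------------------------------

def ml_search(aln: Alignment, max_nni_rounds: int = 50
              ) -> tuple[_UTree, float]:
    """NNI hill climbing from an NJ start; returns the best tree (with
    optimized branch lengths) and its log-likelihood."""
    patterns, weights = np.unique(aln.data, axis=1, return_counts=True)
    patterns = patterns.T.copy()  # (P, n_tips)
    tree = _nj_start(aln, patterns, weights)
    ll = tree.optimize_lengths(2)
    for _ in range(max_nni_rounds):
        m = tree.messages()
        best = None
        for u, v in tree.internal_edges():
            scores, _ = tree.nni_scores(m, u, v)
            cur = scores[0][0]
            for s_ll, which, s_d in scores[1:]:
                gain = s_ll - cur
                if gain > 1e-9 and (best is None or gain > best[0]):
                    best = (gain, u, v, which, s_d)
        if best is None:
            break
        _, u, v, which, s_d = best
        tree.apply_nni(u, v, which, s_d)
        ll = tree.optimize_lengths(1)
    ll = tree.optimize_lengths(2)
    return tree, ll


# ---------------------------------------------------------------------------
# clock-constrained (rooted, ultrametric) ML
# ---------------------------------------------------------------------------

class _ClockTree:
    """Rooted binary tree with tips at height 0 and internal-node heights in
    substitutions/site; branch lengths are height differences (molecular
    clock)."""

    H_CAP = 2.0  # generous upper bound for the root height

    def __init__(self, n_tips: int, labels: list[str],
                 patterns: np.ndarray, weights: np.ndarray):
        self.n = n_tips
        self.labels = labels
        self.patterns = patterns
        self.w = weights.astype(float)
        P = patterns.shape[0]
        self._tipcond = {}
        for i in range(n_tips):
            f = np.zeros((P, 4))
            f[np.arange(P), patterns[:, i]] = 1.0
            self._tipcond[i] = f
        self.parent: dict[int, int | None] = {}
        self.children: dict[int, list[int]] = {}
        self.height: dict[int, float] = {i: 0.0 for i in range(n_tips)}
        self.root: int = -1

    @classmethod
    def from_upgma(cls, aln: Alignment, patterns: np.ndarray,
                   weights: np.ndarray) -> "_ClockTree":
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        n = len(aln.labels)
        D = jc69_distance_matrix(aln)
        Z = linkage(squareform(D, checks=False), method="average")
        t = cls(n, aln.labels, patterns, weights)
        for k, row in enumerate(Z):
            a, b = int(row[0]), int(row[1])
            node = n + k
            t.children[node] = [a, b]
            t.parent[a] = node
            t.parent[b] = node
            h = max(row[2] / 2.0,
                    t.height[a] + 1e-9, t.height[b] + 1e-9)
            t.height[node] = min(h, cls.H_CAP)
        t.root = n + len(Z) - 1
        t.parent[t.root] = None
        return t

    # -- pruning -------------------------------------------------------
    def _evolve(self, f: np.ndarray, d: float) -> np.ndarray:
        x = math.exp(-4.0 * max(d, 0.0) / 3.0)
        return x * f + (1.0 - x) * 0.25 * f.sum(axis=1, keepdims=True)

    def up_messages(self) -> dict[int, np.ndarray]:
        """up[v] = conditional likelihood at v of the subtree below v."""
        up: dict[int, np.ndarray] = {}
        for v in self._postorder():
            if v < self.n:
                up[v] = self._tipcond[v]
            else:
                c1, c2 = self.children[v]
                up[v] = (self._evolve(up[c1], self.height[v] - self.height[c1])
                         * self._evolve(up[c2], self.height[v] - self.height[c2]))
        return up

    def _postorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            if v >= self.n:
                stack.extend(self.children[v])
        return out[::-1]

    def loglike(self, up: dict | None = None) -> float:
        up = up or self.up_messages()
        L = 0.25 * up[self.root].sum(axis=1)
        return float(self.w @ np.log(np.maximum(L, 1e-300)))

    def _evolve_grid(self, f: np.ndarray, dvec: np.ndarray) -> np.ndarray:
        """evolve(f, d) for a vector of branch lengths: (G, P, 4)."""
        x = np.exp(-4.0 * np.maximum(dvec, 0.0) / 3.0)[:, None, None]
        return x * f + (1.0 - x) * 0.25 * f.sum(axis=1, keepdims=True)

    def _gridmax(self, Lvec, lo: float, hi: float,
                 iters: int = 3, pts: int = 17) -> tuple[float, float]:
        """Maximize a vectorized objective by successive grid refinement;
        endpoints are included exactly so boundary maxima are exact."""
        if hi - lo < 1e-12:
            return lo, float(Lvec(np.array([lo]))[0])
        a, b = lo, hi
        best_h, best_ll = lo, -math.inf
        for _ in range(iters):
            hs = np.linspace(a, b, pts)
            ls = Lvec(hs)
            k = int(np.argmax(ls))
            if ls[k] > best_ll:
                best_ll, best_h = float(ls[k]), float(hs[k])
            step = (b - a) / (pts - 1)
            a = max(lo, best_h - step)
            b = min(hi, best_h + step)
        return best_h, best_ll

    def _opt_height(self, fabove: np.ndarray, up1: np.ndarray, h1: float,
                    up2: np.ndarray, h2: float, lo: float, hi: float
                    ) -> tuple[float, float]:
        """Maximize the likelihood over the height of a node with children
        at heights h1, h2 (conditionals up1, up2) and 'rest of tree'
        conditional ``fabove`` at the node."""
        logw = self.w

        def Lvec(hs):
            B = (self._evolve_grid(up1, hs - h1)
                 * self._evolve_grid(up2, hs - h2))
            L = (fabove[None] * B).sum(axis=2)
            return np.log(np.maximum(L, 1e-300)) @ logw

        return self._gridmax(Lvec, lo, hi)

    def optimize_heights(self, n_sweeps: int = 2) -> float:
        """Top-down coordinate ascent on node heights; ``down`` messages
        (conditional of the rest of the tree at each node) are propagated
        with already-updated heights above."""
        ll = -math.inf
        P = self.patterns.shape[0]
        for _ in range(n_sweeps):
            up = self.up_messages()
            down: dict[int, np.ndarray] = {
                self.root: np.full((P, 4), 0.25)}
            order = [v for v in reversed(self._postorder()) if v >= self.n]
            for v in order:
                c1, c2 = self.children[v]
                lo = max(self.height[c1], self.height[c2])
                hi = self.H_CAP if v == self.root else self.height[self.parent[v]]
                h, ll = self._opt_height(down[v], up[c1], self.height[c1],
                                         up[c2], self.height[c2], lo, hi)
                self.height[v] = h
                up[v] = (self._evolve(up[c1], h - self.height[c1])
                         * self._evolve(up[c2], h - self.height[c2]))
                for c, s in ((c1, c2), (c2, c1)):
                    if c >= self.n:
                        g = down[v] * self._evolve(up[s],
                                                   h - self.height[s])
                        down[c] = self._evolve(g, h - self.height[c])
        return ll

    # -- NNI -----------------------------------------------------------
    def _nni_candidates(self):
        """(v, sibling, keep_child, move_child) for each internal non-root
        node and each of its children."""
        out = []
        for v in self._postorder():
            if v < self.n or v == self.root:
                continue
            p = self.parent[v]
            s = [c for c in self.children[p] if c != v][0]
            c1, c2 = self.children[v]
            out.append((v, p, s, c1, c2))
        return out

    def score_nni(self, up: dict, gmsg: dict, v: int, p: int, s: int,
                  keep: int, move: int) -> tuple[float, float, float]:
        """Score swapping sibling ``s`` with child ``move`` of ``v`` (so v's
        children become (keep, s) and p's become (v, move)), jointly
        re-optimizing the heights of v and p by short coordinate ascent.
        Returns (lnL, h_v, h_p)."""
        pp = self.parent[p]
        h_pp = self.H_CAP if pp is None else self.height[pp]
        P = self.patterns.shape[0]
        above = (np.full((P, 4), 0.25) if pp is None else gmsg[p])
        h_move, h_keep, h_s = (self.height[move], self.height[keep],
                               self.height[s])
        hv, hp = self.height[v], self.height[p]
        lo_v = max(h_keep, h_s)
        if hp < lo_v:
            hp = min(h_pp, lo_v + 1e-9)
            if hp < lo_v:  # infeasible under the clock
                return -math.inf, hv, hp
        logw = self.w

        def L_hv(hs, hp_):
            A = (above if pp is None
                 else self._evolve(above, h_pp - hp_))
            A = A * self._evolve(up[move], hp_ - h_move)
            B = (self._evolve_grid(up[keep], hs - h_keep)
                 * self._evolve_grid(up[s], hs - h_s))
            Bp = self._evolve_grid_from(B, hp_ - hs)
            val = (A[None] * Bp).sum(axis=2)
            return np.log(np.maximum(val, 1e-300)) @ logw

        def L_hp(hs, hv_):
            B = (self._evolve(up[keep], hv_ - h_keep)
                 * self._evolve(up[s], hv_ - h_s))
            A = (np.repeat(above[None], len(hs), axis=0) if pp is None
                 else self._evolve_grid(above, h_pp - hs))
            val = (A * self._evolve_grid(up[move], hs - h_move)
                   * self._evolve_grid(B, hs - hv_)).sum(axis=2)
            return np.log(np.maximum(val, 1e-300)) @ logw

        hv, ll = self._gridmax(lambda hs: L_hv(hs, hp), lo_v, hp)
        hp, ll = self._gridmax(lambda hs: L_hp(hs, hv),
                               max(hv, h_move), h_pp)
        hv, ll = self._gridmax(lambda hs: L_hv(hs, hp), lo_v, hp)
        return ll, hv, hp

    def score_nni_quick(self, up: dict, gmsg: dict, v: int, p: int, s: int,
                        keep: int, move: int) -> tuple[float, float]:
        """Cheap rearrangement score: only v's height re-optimized, p's
        height (and the rest) fixed."""
        pp = self.parent[p]
        h_pp = self.H_CAP if pp is None else self.height[pp]
        P = self.patterns.shape[0]
        above = (np.full((P, 4), 0.25) if pp is None else gmsg[p])
        hp = self.height[p]
        h_move, h_keep, h_s = (self.height[move], self.height[keep],
                               self.height[s])
        lo_v = max(h_keep, h_s)
        if hp < lo_v:
            return -math.inf, self.height[v]
        logw = self.w
        A = (above if pp is None else self._evolve(above, h_pp - hp))
        A = A * self._evolve(up[move], hp - h_move)

        def Lvec(hs):
            B = (self._evolve_grid(up[keep], hs - h_keep)
                 * self._evolve_grid(up[s], hs - h_s))
            Bp = self._evolve_grid_from(B, hp - hs)
            val = (A[None] * Bp).sum(axis=2)
            return np.log(np.maximum(val, 1e-300)) @ logw

        h, ll = self._gridmax(Lvec, lo_v, hp, iters=2)
        return ll, h

    def _evolve_grid_from(self, F: np.ndarray, dvec: np.ndarray) -> np.ndarray:
        """evolve each slice F[g] by its own branch length dvec[g]."""
        x = np.exp(-4.0 * np.maximum(dvec, 0.0) / 3.0)[:, None, None]
        return x * F + (1.0 - x) * 0.25 * F.sum(axis=2, keepdims=True)

    def down_messages(self, up: dict
                      ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
        """down[v]: conditional at v of everything outside v's subtree;
        gmsg[c]: the same quantity evaluated at c's parent (pre-evolution
        across the parent-c edge)."""
        P = self.patterns.shape[0]
        down: dict[int, np.ndarray] = {self.root: np.full((P, 4), 0.25)}
        gmsg: dict[int, np.ndarray] = {}
        for v in reversed(self._postorder()):
            if v < self.n:
                continue
            c1, c2 = self.children[v]
            for c, s in ((c1, c2), (c2, c1)):
                g = down[v] * self._evolve(up[s],
                                           self.height[v] - self.height[s])
                gmsg[c] = g
                down[c] = self._evolve(g, self.height[v] - self.height[c])
        return down, gmsg

    def apply_nni(self, v: int, p: int, s: int, keep: int, move: int,
                  new_hv: float, new_hp: float) -> None:
        self.children[p] = [c if c != s else move for c in self.children[p]]
        self.children[v] = [keep, s]
        self.parent[s] = v
        self.parent[move] = p
        self.height[v] = new_hv
        self.height[p] = new_hp

    def current_nni_score(self, up: dict, down: dict, v: int, p: int,
                          s: int, c1: int, c2: int) -> float:
        g = down[p] * self._evolve(up[s], self.height[p] - self.height[s])
        A = self._evolve(g, self.height[p] - self.height[v])
        B = (self._evolve(up[c1], self.height[v] - self.height[c1])
             * self._evolve(up[c2], self.height[v] - self.height[c2]))
        L = (A * B).sum(axis=1)
        return float(self.w @ np.log(np.maximum(L, 1e-300)))

    def to_tree(self) -> Tree:
        def rec(v: int) -> Node:
            if v < self.n:
                return Node(self.labels[v])
            return Node(None, None, [rec(c) for c in self.children[v]])
        return Tree(rec(self.root))

    def copy(self) -> "_ClockTree":
        t = _ClockTree.__new__(_ClockTree)
        t.n, t.labels, t.patterns, t.w = self.n, self.labels, self.patterns, self.w
        t._tipcond = self._tipcond
        t.parent = dict(self.parent)
        t.children = {k: list(v) for k, v in self.children.items()}
        t.height = dict(self.height)
        t.root = self.root
        return t


def clock_ml_search(aln: Alignment, max_nni_rounds: int = 50
                    ) -> tuple[_ClockTree, float]:
    """Clock-constrained JC69 ML: UPGMA start, node-height coordinate
    ascent, rooted-NNI hill climbing."""
    patterns, weights = np.unique(aln.data, axis=1, return_counts=True)
    patterns = patterns.T.copy()
    tree = _ClockTree.from_upgma(aln, patterns, weights)
    ll = tree.optimize_heights(2)
    for _ in range(max_nni_rounds):
        up = tree.up_messages()
        down, gmsg = tree.down_messages(up)
        # cheap pass: score each rearrangement with only the focal node's
        # height re-optimized; shortlist for joint (node, parent) scoring
        quick = []
        for v, p, s, c1, c2 in tree._nni_candidates():
            cur = tree.current_nni_score(up, down, v, p, s, c1, c2)
            for keep, move in ((c1, c2), (c2, c1)):
                alt, hv = tree.score_nni_quick(up, gmsg, v, p, s, keep, move)
                quick.append((alt - cur, v, p, s, keep, move))
        quick.sort(reverse=True)
        cands = []
        for gain0, v, p, s, keep, move in quick[:4]:
            if gain0 < -2.0:
                break
            alt, hv, hp = tree.score_nni(up, gmsg, v, p, s, keep, move)
            cur = tree.current_nni_score(up, down, v, p, s,
                                         *tree.children[v])
            if alt - cur > 1e-9:
                cands.append((alt - cur, v, p, s, keep, move, hv, hp))
        cands.sort(reverse=True)
        accepted = False
        for gain, v, p, s, keep, move, hv, hp in cands[:2]:
            snapshot = tree.copy()
            tree.apply_nni(v, p, s, keep, move, hv, hp)
            ll_new = tree.optimize_heights(1)
            if ll_new > ll + 1e-9:
                ll = ll_new
                accepted = True
                break
            tree = snapshot
        if not accepted:
            break
    ll = tree.optimize_heights(3)
    return tree, ll


def estimate_gene_tree(aln: Alignment, tmap: TaxonMap, outgroup_species: str,
                       tie_tol: float = 1e-6, max_tied: int = 64) -> Tree:
    """ML gene-tree topology under JC69 with a molecular clock (rooted,
    ultrametric), matching the generating model of the study design.

    Ties within ``tie_tol`` log-units (assessed over the rooted-NNI
    neighborhood of the ML tree with the rearranged node's height
    re-optimized) are resolved by semi-strict consensus, so the returned
    topology may be multifurcating.  The outgroup is used as a fallback
    root check only; under the clock the root position is estimated."""
    if aln.n_sites < 1:
        raise TreeError("alignment must contain at least one site")
    outgroup = [x for x in tmap.individuals_of(outgroup_species)
                if x in aln.labels]
    if not outgroup:
        raise TreeError(f"no outgroup individuals ({outgroup_species}) in "
                        "the alignment")
    tree, ll = clock_ml_search(aln)
    up = tree.up_messages()
    down, gmsg = tree.down_messages(up)
    tied: list[Tree] = []
    for v, p, s, c1, c2 in tree._nni_candidates():
        cur = tree.current_nni_score(up, down, v, p, s, c1, c2)
        ref = max(cur, ll)
        for keep, move in ((c1, c2), (c2, c1)):
            alt_ll, hv, hp = tree.score_nni(up, gmsg, v, p, s, keep, move)
            if alt_ll >= ref - tie_tol:
                alt = tree.copy()
                alt.apply_nni(v, p, s, keep, move, hv, hp)
                tied.append(alt.to_tree())
                if len(tied) >= max_tied:
                    break
        if len(tied) >= max_tied:
            break
    candidates = [tree.to_tree()] + tied
    if len(candidates) == 1:
        return candidates[0]
    return semi_strict_consensus(candidates)
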