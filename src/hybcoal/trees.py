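"""Rooted-tree data structures, newick I/O, taxon maps, and consensus utilities.

Gene trees are always handled as *rooted topologies*: branch lengths may be
carried (the simulator produces them) but every probability computation in
this package ignores them.  Tip labels name sampled individuals; a
:class:`TaxonMap` assigns each individual to a species, which is what allows
multiple lineages per species to be modelled.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Iterator, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Tree",
    "GeneTreeSample",
    "TaxonMap",
    "ParentalTree",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_newick_trees",
    "load_taxon_map",
    "semi_strict_consensus",
    "is_binary",
    "resolve_polytomies",
    "root_on_outgroup",
    "enumerate_rooted_topologies",
    "tree_from_clades",
]


class TreeError(ValueError):
    """Invalid tree structure or incompatible inputs."""


class NewickParseError(TreeError):
    """Malformed newick input."""


class Node:
    """A node of a rooted tree.  Tips carry a ``label``; edges may carry a
    ``length`` (the length of the edge *above* this node)."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label: str | None = None, length: float | None = None,
                 children: list["Node"] | None = None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """A rooted tree with string tip labels.

    Used both for gene trees (tips = individuals) and, via
    :class:`~hybcoal.hybridtree.ParentalTree`, species trees (tips = species).
    """

    def __init__(self, root: Node):
        self.root = root
        labels = self.tip_labels_list()
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    # -- traversal -----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels_list(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self.tip_labels_list())

    # -- structure -----------------------------------------------------
    def clades(self, include_trivial: bool = False) -> list[frozenset[str]]:
        """Tip sets of internal nodes (root included).  With
        ``include_trivial`` also the singleton tip clades."""
        out: list[frozenset[str]] = []
        memo: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                memo[id(node)] = frozenset([node.label])
                if include_trivial:
                    out.append(memo[id(node)])
            else:
                cl = frozenset().union(*(memo[id(c)] for c in node.children))
                memo[id(node)] = cl
                out.append(cl)
        return out

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.postorder())

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            return Node(n.label, n.length, [rec(c) for c in n.children])
        return Tree(rec(self.root))

    def topology(self) -> "Tree":
        """A copy with all branch lengths dropped."""
        t = self.copy()
        for n in t.postorder():
            n.length = None
        return t

    def canonical_key(self) -> str:
        """Label-sorted newick-like string; equal iff topologies are equal."""
        def rec(n: Node) -> str:
            if n.is_leaf:
                return n.label
            return "(" + ",".join(sorted(rec(c) for c in n.children)) + ")"
        return rec(self.root) + ";"

    def newick(self, lengths: bool = True) -> str:
        return write_newick(self, lengths=lengths)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.canonical_key()!r})"


# ---------------------------------------------------------------------------
# newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> Tree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or dnode.taxon.label is None:
                raise NewickParseError("unlabeled tip in newick input")
            return Node(str(dnode.taxon.label).replace(" ", "_"),
                        dnode.edge.length)
        return Node(None, dnode.edge.length,
                    [rec(c) for c in dnode.child_nodes()])
    return Tree(rec(dtree.seed_node))


def parse_newick(text: str, expect_branch_lengths: bool = False) -> Tree:
    """Parse a single rooted newick statement.

    Branch lengths present in the input are discarded (with a log notice)
    unless ``expect_branch_lengths`` is set.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  rooting="force-rooted",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"malformed newick: {exc}") from None
    tree = _from_dendropy(dtree)
    has_lengths = any(n.length is not None for n in tree.postorder())
    if has_lengths and not expect_branch_lengths:
        logger.info("branch lengths present in newick input were discarded")
        tree = tree.topology()
    return tree


def write_newick(tree: Tree, lengths: bool = True) -> str:
    def rec(n: Node) -> str:
        if n.is_leaf:
            s = n.label
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
        if lengths and n.length is not None:
            s += f":{n.length:.10g}"
        return s
    return rec(tree.root) + ";"


def read_newick_trees(path: str, expect_branch_lengths: bool = False) -> list[Tree]:
    """Read one tree per ';'-terminated statement (one or more per line)."""
    with open(path) as fh:
        text = fh.read()
    statements = [s.strip() for s in text.split(";") if s.strip()]
    return [parse_newick(s + ";", expect_branch_lengths) for s in statements]


# ---------------------------------------------------------------------------
# taxon map
# ---------------------------------------------------------------------------

class TaxonMap:
    """Assignment of individuals (gene-tree tips) to species."""

    def __init__(self, entries: dict[str, str] | Iterable[tuple[str, str]]):
        if not isinstance(entries, dict):
            d: dict[str, str] = {}
            for ind, sp in entries:
                if ind in d and d[ind] != sp:
                    raise TreeError(
                        f"individual {ind!r} mapped to both {d[ind]!r} and {sp!r}")
                d[ind] = sp
            entries = d
        if not entries:
            raise TreeError("empty taxon map")
        self._map = dict(entries)

    def species_of(self, individual: str) -> str:
        try:
            return self._map[individual]
        except KeyError:
            raise TreeError(f"individual {individual!r} not in taxon map") from None

    def individuals_of(self, species: str) -> list[str]:
        return sorted(i for i, s in self._map.items() if s == species)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._map.values())

    @property
    def individuals(self) -> frozenset[str]:
        return frozenset(self._map)

    def items(self):
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)

    def canonical_key(self) -> str:
        return ";".join(f"{i}={s}" for i, s in sorted(self._map.items()))

    def restrict(self, individuals: Iterable[str]) -> "TaxonMap":
        return TaxonMap({i: self._map[i] for i in individuals})

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# individual\tspecies\n")
            for ind, sp in sorted(self._map.items()):
                fh.write(f"{ind}\t{sp}\n")


def load_taxon_map(path: str) -> TaxonMap:
    """Load a two-column TSV (individual<TAB>species); '#' comments allowed."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise TreeError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    return TaxonMap(pairs)


# ---------------------------------------------------------------------------
# gene-tree samples
# ---------------------------------------------------------------------------

class GeneTreeSample:
    """An ordered multi-locus collection of rooted gene-tree topologies on a
    common individual set.  Branch lengths, if present, are dropped."""

    def __init__(self, trees: Sequence[Tree]):
        if not trees:
            raise TreeError("empty gene-tree sample")
        trees = [t.topology() for t in trees]
        tips0 = trees[0].tip_labels
        for k, t in enumerate(trees):
            if t.tip_labels != tips0:
                missing = tips0 ^ t.tip_labels
                raise TreeError(
                    f"gene tree {k} has a different tip set (difference: {sorted(missing)})")
        self.trees: list[Tree] = list(trees)

    @property
    def N(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        return self.trees[0].tip_labels

    def __iter__(self):
        return iter(self.trees)

    def __len__(self):
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @classmethod
    def from_file(cls, path: str) -> "GeneTreeSample":
        return cls(read_newick_trees(path))

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.newick(lengths=False) + "\n")


# ---------------------------------------------------------------------------
# consensus and resolutions
# ---------------------------------------------------------------------------

def _compatible(c: frozenset, d: frozenset) -> bool:
    inter = c & d
    return not inter or inter == c or inter == d


def tree_from_clades(tips: frozenset[str], clades: Iterable[frozenset[str]]) -> Tree:
    """Build the rooted tree whose internal nodes are exactly the given
    pairwise-compatible, non-trivial, proper clades."""
    clades = sorted(set(clades), key=lambda c: (-len(c), sorted(c)))
    nodes: dict[frozenset, Node] = {tips: Node()}
    parent_of: dict[frozenset, frozenset] = {}
    ordered = [tips] + clades
    for i, c in enumerate(ordered[1:], 1):
        # smallest strict superset among earlier (larger) clades
        best = tips
        for d in ordered[:i]:
            if c < d and len(d) < len(best):
                best = d
        parent_of[c] = best
        nodes[c] = Node()
    children_cl: dict[frozenset, list[frozenset]] = {c: [] for c in nodes}
    for c, p in parent_of.items():
        children_cl[p].append(c)
    for c, node in nodes.items():
        covered = frozenset().union(*children_cl[c]) if children_cl[c] else frozenset()
        kids = [nodes[k] for k in sorted(children_cl[c], key=sorted)]
        kids += [Node(t) for t in sorted(c - covered)]
        node.children = kids
    return Tree(nodes[tips])


def semi_strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Semi-strict (combinable-component) consensus of rooted trees: the tree
    containing every clade that is compatible with *all* input trees."""
    if not trees:
        raise TreeError("no trees given for consensus")
    tips = trees[0].tip_labels
    for t in trees:
        if t.tip_labels != tips:
            raise TreeError("consensus inputs have differing tip sets")
    clade_sets = [set(t.clades()) for t in trees]
    candidates = set().union(*clade_sets)
    candidates = {c for c in candidates if 1 < len(c) < len(tips)}
    kept = [c for c in candidates
            if all(all(_compatible(c, d) for d in cs) for cs in clade_sets)]
    return tree_from_clades(tips, kept)


def is_binary(tree: Tree) -> bool:
    return tree.is_binary()


def _rooted_shapes(items: Sequence) -> list:
    """All rooted binary shapes over the given items, as nested 2-tuples."""
    if len(items) == 1:
        return [items[0]]
    out = []
    first, rest = items[0], list(items[1:])
    for shape in _rooted_shapes(rest):
        for edited in _insert_everywhere(shape, first):
            out.append(edited)
    return out


def _insert_everywhere(shape, item) -> list:
    """Attach ``item`` on every edge of ``shape`` including above the root."""
    results = [(item, shape)]
    if isinstance(shape, tuple):
        a, b = shape
        results += [(x, b) for x in _insert_everywhere(a, item)]
        results += [(a, x) for x in _insert_everywhere(b, item)]
    return results


def resolve_polytomies(tree: Tree, cap: int = 20000) -> list[Tree]:
    """Enumerate all binary resolutions of a rooted tree.

    Raises :class:`TreeError` if the count would exceed ``cap`` (advice:
    re-estimate the gene tree rather than marginalizing a near-star tree).
    """
    def double_factorial(m):
        out = 1
        for k in range(m, 1, -2):
            out *= k
        return out

    total = 1
    for n in tree.postorder():
        if len(n.children) > 2:
            total *= double_factorial(2 * len(n.children) - 3)
            if total > cap:
                raise TreeError(
                    f"number of binary resolutions exceeds cap ({cap}); "
                    "re-estimate this gene tree")

    def rec(node: Node) -> list[Node]:
        if node.is_leaf:
            return [Node(node.label)]
        child_variants = [rec(c) for c in node.children]
        out = []
        for combo in itertools.product(*child_variants):
            if len(combo) <= 2:
                out.append(Node(None, None, list(combo)))
                continue
            for shape in _rooted_shapes(list(range(len(combo)))):
                def build(s) -> Node:
                    if isinstance(s, int):
                        return combo_copy(combo[s])
                    return Node(None, None, [build(s[0]), build(s[1])])
                out.append(build(shape))
        return out

    def combo_copy(n: Node) -> Node:
        return Node(n.label, None, [combo_copy(c) for c in n.children])

    resolved = [Tree(r) for r in rec(tree.root)]
    # deduplicate (polytomy shapes can coincide after labeling only if the
    # tree had repeated structure; cheap safety)
    seen, out = set(), []
    for t in resolved:
        k = t.canonical_key()
        if k not in seen:
            seen.add(k)
            out.append(t)
    return out


def root_on_outgroup(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Re-root a tree so the outgroup individuals form (part of) one side of
    the root.

    The input is interpreted as unrooted.  If some edge splits exactly the
    outgroup set from the rest, the root is placed on that edge; otherwise the
    edge whose split is closest to the outgroup set (fewest mismatches, ties
    broken deterministically) is used.
    """
    og = frozenset(outgroup)
    tips = tree.tip_labels
    if not og or not og < tips:
        raise TreeError("outgroup must be a non-empty proper subset of tips")

    # collect candidate splits from the unrooted version: every edge of the
    # rooted input except the root's own edges defines a split; root-child
    # edges coincide.
    best = None
    for tr, side in _unrooted_splits(tree):
        miss = min(len(side ^ og), len(side ^ (tips - og)))
        key = (miss, len(side), tuple(sorted(side)))
        if best is None or key < best[0]:
            best = (key, tr)
    return best[1]


def _unrooted_splits(tree: Tree):
    """Yield (rerooted_tree, outgroup_side_tipset) for each edge of the
    unrooted version of ``tree``."""
    # Strategy: for each node (except root), re-root on the edge above it.
    t = tree.topology()
    nodes = list(t.postorder())
    for node in nodes:
        if node is t.root:
            continue
        yield _reroot_on_edge(t, node), _tipset(node)


def _tipset(node: Node) -> frozenset[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        stack.extend(n.children)
    return frozenset(out)


def _reroot_on_edge(tree: Tree, target: Node) -> Tree:
    """Root the (unrooted reading of) ``tree`` on the edge above ``target``."""
    parent_of: dict[int, Node] = {}
    for n in tree.postorder():
        for c in n.children:
            parent_of[id(c)] = n

    def clone_down(n: Node, skip: Node | None) -> Node:
        return Node(n.label, None,
                    [clone_down(c, None) for c in n.children if c is not skip])

    def clone_up(n: Node, came_from: Node) -> Node | None:
        """Subtree seen looking 'up' from n (excluding came_from)."""
        kids = [clone_down(c, None) for c in n.children if c is not came_from]
        p = parent_of.get(id(n))
        if p is not None:
            up = clone_up(p, n)
            if up is not None:
                kids.append(up)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # suppress unary node (old root)
        return Node(None, None, kids)

    below = clone_down(target, None)
    above = clone_up(parent_of[id(target)], target)
    if above is None:
        return Tree(below)
    return Tree(Node(None, None, [below, above]))


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

class ParentalTree:
    """A rooted ultrametric species tree with node heights in coalescent
    units (2Ne generations); tips sit at height 0.

    Edge lengths on the wrapped :class:`Tree` give branch durations; heights
    are derived and validated.  Each branch (the edge above a non-root node,
    plus the infinite branch above the root) is one panmictic population.
    """

    _ULTRAMETRIC_TOL = 1e-6

    def __init__(self, tree: Tree):
        self.tree = tree
        self.heights: dict[int, float] = {}
        for node in tree.postorder():
            if node.is_leaf:
                self.heights[id(node)] = 0.0
                continue
            hs = []
            for c in node.children:
                if c.length is None or c.length < 0:
                    raise TreeError("species tree requires nonnegative branch lengths")
                hs.append(self.heights[id(c)] + c.length)
            if max(hs) - min(hs) > self._ULTRAMETRIC_TOL * max(1.0, max(hs)):
                raise TreeError(f"species tree not ultrametric at clade "
                                f"{sorted(_tipset(node))}: heights {hs}")
            h = sum(hs) / len(hs)
            for c in node.children:  # snap to exact ultrametricity
                c.length = h - self.heights[id(c)]
            self.heights[id(node)] = h
        # branches = edges above non-root nodes, in postorder
        self.branch_nodes: list[Node] = [n for n in tree.postorder()
                                         if n is not tree.root]

    @classmethod
    def from_newick(cls, text: str) -> "ParentalTree":
        return cls(parse_newick(text, expect_branch_lengths=True))

    @property
    def species(self) -> frozenset[str]:
        return self.tree.tip_labels

    @property
    def root_height(self) -> float:
        return self.heights[id(self.tree.root)]

    def durations(self):
        """Branch durations aligned with :attr:`branch_nodes` (root branch,
        of infinite duration, excluded)."""
        import numpy as np
        return np.array([n.length for n in self.branch_nodes], dtype=float)

    def topology_key(self) -> str:
        return self.tree.canonical_key()

    def newick(self) -> str:
        return self.tree.newick(lengths=True)


# ---------------------------------------------------------------------------
# topology enumeration (used by coalprob.all_topology_probs and tests)
# ---------------------------------------------------------------------------

def enumerate_rooted_topologies(labels: Sequence[str]) -> list[Tree]:
    """All rooted binary labeled topologies on the given tips
    ((2n-3)!! of them)."""
    labels = sorted(labels)
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate labels")

    def build(shape) -> Node:
        if isinstance(shape, str):
            return Node(shape)
        return Node(None, None, [build(shape[0]), build(shape[1])])

    return [Tree(build(s)) for s in _rooted_shapes(labels)]
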