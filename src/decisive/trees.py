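"""Leaf-labelled phylogenetic trees as clade / split systems.

A rooted tree on leaf set L is stored as its set of nontrivial clades
(subsets C with 2 <= |C| < |L|); an unrooted tree as its set of nontrivial
splits (unordered bipartitions with both sides of size >= 2).  These systems
are in bijection with tree topologies (laminar families for rooted trees,
pairwise-compatible split systems for unrooted ones), which turns the
operations that matter for decisiveness -- restriction, display, edge
distinguishing -- into plain set algebra.  Branch lengths are deliberately
ignored: decisiveness is purely topological.

Newick text is parsed through dendropy; writing is done directly from the
clade system with a deterministic child order.
"""
from __future__ import annotations

from itertools import combinations
from math import prod
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

from ._utils import GuardError, as_rng

#: default guards on exhaustive tree enumeration
ENUM_GUARD_ROOTED = 9
ENUM_GUARD_UNROOTED = 10

Clade = frozenset
Split = frozenset  # frozenset({sideA, sideB})


class PhyloTree:
    """A rooted or unrooted leaf-labelled tree (binary or multifurcating).

    Internal edges are canonically identified by the clade (rooted) or split
    (unrooted) they induce, so edge sets are directly comparable across
    trees on the same labels.
    """

    __slots__ = ("leaves", "rooted", "groups")

    def __init__(self, leaves, groups=(), *, rooted: bool, validate: bool = True):
        leaves = frozenset(str(x) for x in leaves)
        if not leaves:
            raise ValueError("a tree needs at least one leaf")
        groups = frozenset(groups)
        object.__setattr__(self, "leaves", leaves)
        object.__setattr__(self, "rooted", bool(rooted))
        object.__setattr__(self, "groups", groups)
        if validate:
            self._validate()

    def _validate(self):
        n = len(self.leaves)
        if self.rooted:
            for c in self.groups:
                if not (isinstance(c, frozenset) and c <= self.leaves):
                    raise ValueError(f"clade {c!r} is not a subset of the leaves")
                if not 2 <= len(c) <= n - 1:
                    raise ValueError(f"clade {set(c)} is trivial for n={n}")
            for a, b in combinations(self.groups, 2):
                if a & b and not (a <= b or b <= a):
                    raise ValueError(f"clades {set(a)} and {set(b)} overlap")
        else:
            for s in self.groups:
                sides = tuple(s)
                if len(sides) != 2:
                    raise ValueError(f"split {s!r} must have two sides")
                a, b = sides
                if a | b != self.leaves or a & b:
                    raise ValueError(f"split {s!r} does not bipartition the leaves")
                if min(len(a), len(b)) < 2:
                    raise ValueError(f"split {s!r} is trivial")
            for s, t in combinations(self.groups, 2):
                a, b = tuple(s)
                c, d = tuple(t)
                if all((x & y) for x in (a, b) for y in (c, d)):
                    raise ValueError(f"incompatible splits {s!r} and {t!r}")

    def __setattr__(self, *a):
        raise AttributeError("PhyloTree is immutable")

    @property
    def n(self) -> int:
        return len(self.leaves)

    @property
    def internal_edges(self) -> frozenset:
        """Internal edges, keyed by clade (rooted) or split (unrooted)."""
        return self.groups

    @property
    def is_binary(self) -> bool:
        need = self.n - 2 if self.rooted else self.n - 3
        return len(self.groups) == max(need, 0)

    def __eq__(self, other):
        return (
            isinstance(other, PhyloTree)
            and self.rooted == other.rooted
            and self.leaves == other.leaves
            and self.groups == other.groups
        )

    def __hash__(self):
        return hash((self.rooted, self.leaves, self.groups))

    def __repr__(self):
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind} {write_newick(self)!r}>"

    # conveniences delegating to module functions
    def restrict(self, Y) -> "PhyloTree":
        return restrict(self, Y)

    def displays(self, other: "PhyloTree") -> bool:
        return displays(self, other)


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, rooted: Optional[bool] = None) -> PhyloTree:
    """Parse one Newick tree.

    ``rooted=None`` infers rootedness from the basal vertex: a degree-2 root
    means rooted, a basal polytomy means unrooted.  Branch lengths and
    internal labels are parsed and discarded.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in newick input")
    leaves = frozenset(labels)
    n = len(leaves)
    seed = dt.seed_node
    basal = len(seed.child_nodes())
    if rooted is None:
        rooted = basal == 2 or n <= 2
    node_sets = []
    for node in dt.preorder_node_iter():
        if node is seed or node.is_leaf():
            continue
        node_sets.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    if rooted:
        groups = {c for c in node_sets if 2 <= len(c) <= n - 1}
    else:
        groups = {
            frozenset({c, leaves - c})
            for c in node_sets
            if 2 <= len(c) <= n - 2
        }
    return PhyloTree(leaves, groups, rooted=rooted)


def _partition(block: frozenset, groups: Iterable[frozenset]) -> list[frozenset]:
    """Maximal sub-blocks of ``block``: child clades plus leftover singletons."""
    inside = [g for g in groups if g < block]
    maximal = [g for g in inside if not any(g < h for h in inside)]
    rest = block - frozenset().union(*maximal) if maximal else block
    return maximal + [frozenset({x}) for x in rest]


def _rooted_newick(block: frozenset, groups) -> str:
    if len(block) == 1:
        return next(iter(block))
    parts = sorted(_partition(block, groups), key=min)
    return "(" + ",".join(_rooted_newick(p, groups) for p in parts) + ")"


def write_newick(tree: PhyloTree) -> str:
    """Deterministic Newick text (children sorted by smallest label)."""
    if tree.rooted:
        return _rooted_newick(tree.leaves, tree.groups) + ";"
    if tree.n == 1:
        return next(iter(tree.leaves)) + ";"
    anchor = min(tree.leaves)
    rest = tree.leaves - {anchor}
    rel = [next(s for s in sp if anchor not in s) for sp in tree.groups]
    if tree.n == 2:
        return "(" + ",".join(sorted(tree.leaves)) + ");"
    parts = sorted(_partition(rest, rel), key=min)
    inner = ",".join(_rooted_newick(p, rel) for p in parts)
    return f"({anchor},{inner});"


# ---------------------------------------------------------------------------
# rooted <-> unrooted conversion

def root_at(tree: PhyloTree, leaf: str) -> PhyloTree:
    """Root an unrooted tree at ``leaf``: the rooted tree on leaves - {leaf}."""
    if tree.rooted:
        raise ValueError("tree is already rooted")
    if leaf not in tree.leaves:
        raise ValueError(f"unknown leaf {leaf!r}")
    if tree.n < 2:
        raise ValueError("cannot root a single-leaf tree")
    clades = {next(s for s in sp if leaf not in s) for sp in tree.groups}
    return PhyloTree(tree.leaves - {leaf}, clades, rooted=True, validate=False)


def unroot_with(tree: PhyloTree, leaf: str) -> PhyloTree:
    """Attach ``leaf`` above the root: the unrooted tree on leaves + {leaf}."""
    if not tree.rooted:
        raise ValueError("tree is already unrooted")
    if leaf in tree.leaves:
        raise ValueError(f"label {leaf!r} already present")
    leaves = tree.leaves | {leaf}
    splits = {frozenset({c, leaves - c}) for c in tree.groups}
    return PhyloTree(leaves, splits, rooted=False, validate=False)


# ---------------------------------------------------------------------------
# restriction and display


def restrict(tree: PhyloTree, Y) -> PhyloTree:
    """The induced tree T|Y (connect Y, suppress degree-2 vertices)."""
    Y = frozenset(str(x) for x in Y)
    unknown = Y - tree.leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if not Y:
        raise ValueError("restriction to an empty set")
    m = len(Y)
    if tree.rooted:
        groups = {c & Y for c in tree.groups if 2 <= len(c & Y) <= m - 1}
    else:
        groups = set()
        for sp in tree.groups:
            a, b = tuple(sp)
            a, b = a & Y, b & Y
            if len(a) >= 2 and len(b) >= 2:
                groups.add(frozenset({a, b}))
    return PhyloTree(Y, groups, rooted=tree.rooted, validate=False)


def displays(T: PhyloTree, t: PhyloTree) -> bool:
    """True iff T|leaves(t) equals t or resolves it.

    Every clade (split) of ``t`` must be a clade (split) of the restriction.
    """
    if T.rooted != t.rooted:
        raise ValueError("cannot compare rooted with unrooted trees")
    if not t.leaves <= T.leaves:
        raise ValueError("t has leaves not present in T")
    return t.groups <= restrict(T, t.leaves).groups


# ---------------------------------------------------------------------------
# edge neighbourhoods and distinguishing


def _children_map(leaves: frozenset, groups: frozenset) -> dict:
    """Map each clade (and the root, keyed by ``leaves``) to its child blocks."""
    nodes = sorted(groups, key=len)
    parent = {}
    for i, c in enumerate(nodes):
        parent[c] = next((d for d in nodes[i + 1:] if c < d), leaves)
    children: dict = {leaves: []}
    for c in nodes:
        children.setdefault(c, [])
        children[parent[c]] = children.get(parent[c], [])
        children[parent[c]].append(c)
    for x in leaves:
        p = next((d for d in nodes if x in d), leaves)
        children[p].append(frozenset({x}))
    return children


def edge_blocks(tree: PhyloTree) -> dict:
    """Leaf-set blocks of the subtrees hanging off each internal edge.

    Rooted: for the edge above clade C, the blocks are C's child subtrees
    plus C's sibling subtrees -- the subtrees incident with the edge that do
    not contain the root.  Unrooted: the subtrees incident with both ends of
    the split.  Requires a binary tree, where these are 3 and 4 blocks.
    """
    if not tree.is_binary:
        raise ValueError("edge blocks are defined for binary trees only")
    out = {}
    if tree.rooted:
        children = _children_map(tree.leaves, tree.groups)
        nodes = sorted(tree.groups, key=len)
        for c in tree.groups:
            p = next((d for d in nodes if c < d), tree.leaves)
            siblings = [b for b in children[p] if b != c]
            out[c] = tuple(children[c]) + tuple(siblings)
    else:
        sides = [s for sp in tree.groups for s in sp]
        for sp in tree.groups:
            blocks = []
            for side in sp:
                inside = [s for s in sides if s < side]
                maximal = [s for s in inside if not any(s < h for h in inside)]
                rest = side - frozenset().union(*maximal) if maximal else side
                blocks.extend(maximal + [frozenset({x}) for x in rest])
            out[sp] = tuple(blocks)
    return out


def distinguished_edges(T: PhyloTree, Y) -> frozenset:
    """Internal edges of binary T distinguished by the restriction T|Y.

    An edge is distinguished when Y touches every subtree incident with it
    (ignoring the root-side subtree in the rooted case), i.e. when some
    quartet (rooted triple) drawn from Y separates across the edge.
    """
    Y = frozenset(str(x) for x in Y)
    unknown = Y - T.leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    blocks = edge_blocks(T)
    return frozenset(e for e, bl in blocks.items() if all(b & Y for b in bl))


def edge_distinguished_by(T: PhyloTree, edge, t: PhyloTree, blocks=None) -> bool:
    """Is the internal edge of rooted binary T distinguished by input tree t?

    True when t's leaf set touches all non-root subtrees at the edge *and*
    the corresponding edge survives in t (its induced clade is a clade of
    t).  For a fully resolved restriction t = T|Y the second part is
    automatic; for partially collapsed inputs it is the whole point.
    """
    if not T.rooted:
        raise ValueError("edge_distinguished_by applies to rooted trees")
    bl = (blocks or edge_blocks(T))[edge]
    Y = t.leaves
    if not all(b & Y for b in bl):
        return False
    return (edge & Y) in t.groups


# ---------------------------------------------------------------------------
# defining a tree


def _rooted_triples(t: PhyloTree) -> set:
    """Resolved rooted triples ab|c of t, as (frozenset({a,b}), c)."""
    # ab|c holds iff some clade contains a,b but not c; the union over all
    # clades enumerates exactly the resolved triples
    trips = set()
    for g in t.groups:
        outside = t.leaves - g
        for a, b in combinations(g, 2):
            pair = frozenset({a, b})
            # ab|c iff the smallest clade containing a,b excludes c
            for c in outside:
                trips.add((pair, c))
    return trips


def _build(taxa: frozenset, triples: set) -> Optional[frozenset]:
    """Aho BUILD: minimal rooted tree (as a clade set) displaying `triples`.

    Returns None when the triples are incompatible.
    """
    clades: set = set()

    def rec(S: frozenset) -> bool:
        if len(S) <= 2:
            return True
        # union-find over S with an edge a-b for each triple ab|c inside S
        parent = {x: x for x in S}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for pair, c in triples:
            if c in S and pair <= S:
                a, b = tuple(pair)
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        comps: dict = {}
        for x in S:
            comps.setdefault(find(x), []).append(x)
        if len(comps) == 1:
            return False
        for comp in comps.values():
            fc = frozenset(comp)
            if len(fc) >= 2:
                if fc != S:
                    clades.add(fc)
                if not rec(fc):
                    return False
        return True

    ok = rec(taxa)
    return frozenset(clades) if ok else None


def defines(
    inputs: Sequence[PhyloTree],
    X=None,
    candidate: Optional[PhyloTree] = None,
    guard: int = ENUM_GUARD_UNROOTED,
) -> tuple[bool, Optional[PhyloTree]]:
    """Do the input trees define a unique tree on X?

    Rooted inputs: a candidate supertree is assembled with the BUILD
    algorithm (or supplied) and checked by the display + all-edges-
    distinguished criterion, which characterizes defining for rooted trees.
    Unrooted inputs: edge distinguishing is only necessary, so uniqueness is
    decided by brute-force enumeration of all binary trees on X (guarded).

    Returns ``(defined, tree)`` with the defined tree when it exists.
    """
    if not inputs:
        raise ValueError("no input trees")
    rooted = inputs[0].rooted
    if any(t.rooted != rooted for t in inputs):
        raise ValueError("mixed rooted/unrooted inputs")
    union = frozenset().union(*(t.leaves for t in inputs))
    if X is None:
        X = union
    else:
        X = frozenset(str(x) for x in X)
        if union != X:
            raise ValueError("union of input leaf sets differs from X")
    if rooted:
        if candidate is None:
            triples = set().union(*(_rooted_triples(t) for t in inputs))
            clades = _build(X, triples)
            if clades is None:
                return False, None
            candidate = PhyloTree(X, clades, rooted=True, validate=False)
        if candidate.leaves != X or not candidate.rooted:
            raise ValueError("candidate must be a rooted tree on X")
        if not candidate.is_binary:
            return False, None
        if not all(displays(candidate, t) for t in inputs):
            return False, None
        blocks = edge_blocks(candidate)
        for e in candidate.groups:
            if not any(edge_distinguished_by(candidate, e, t, blocks) for t in inputs):
                return False, None
        return True, candidate
    # unrooted: brute force
    n = len(X)
    if n > guard:
        raise GuardError(
            f"brute-force uniqueness on n={n} unrooted leaves exceeds the guard "
            f"({guard})"
        )
    found = None
    for T in enumerate_trees(sorted(X), rooted=False, guard=guard):
        if all(displays(T, t) for t in inputs):
            if found is not None:
                return False, None
            found = T
    return (found is not None), found


# ---------------------------------------------------------------------------
# enumeration, counting, random generation


def count_trees(n: int, rooted: bool) -> int:
    """(2n-3)!! rooted / (2n-5)!! unrooted binary topologies on n labels."""
    if rooted:
        if n < 1:
            raise ValueError("n >= 1 required")
        return prod(range(1, 2 * n - 2, 2)) if n >= 2 else 1
    if n < 3:
        raise ValueError("unrooted trees need n >= 3")
    return prod(range(1, 2 * n - 4, 2)) if n >= 4 else 1


def _rooted_clade_sets(labels: Sequence[str]) -> Iterator[frozenset]:
    n = len(labels)
    if n <= 2:
        yield frozenset()
        return

    def gen(i: int) -> Iterator[frozenset]:
        if i == 2:
            yield frozenset()
            return
        x = labels[i - 1]
        prev = labels[: i - 1]
        prevset = frozenset(prev)
        attach_points = [frozenset({y}) for y in prev]
        for clades in gen(i - 1):
            yield frozenset(clades | {prevset})  # new root above the old one
            for g in attach_points + sorted(clades, key=lambda c: (len(c), sorted(c))):
                new = {(c | {x}) if g < c else c for c in clades}
                new.add(g | {x})
                yield frozenset(new)

    yield from gen(n)


def enumerate_trees(
    labels: Sequence[str], rooted: bool, guard: Optional[int] = None
) -> Iterator[PhyloTree]:
    """All binary topologies on ``labels``, duplicate-free, guarded by size."""
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    if guard is None:
        guard = ENUM_GUARD_ROOTED if rooted else ENUM_GUARD_UNROOTED
    if n > guard:
        raise GuardError(f"enumeration of n={n} exceeds the guard ({guard})")
    if rooted:
        leaves = frozenset(labels)
        for clades in _rooted_clade_sets(labels):
            yield PhyloTree(leaves, clades, rooted=True, validate=False)
    else:
        if n < 3:
            raise ValueError("unrooted trees need n >= 3")
        anchor = labels[-1]
        for clades in _rooted_clade_sets(labels[:-1]):
            t = PhyloTree(frozenset(labels[:-1]), clades, rooted=True, validate=False)
            yield unroot_with(t, anchor)


def random_tree(labels: Sequence[str], rooted: bool, rng) -> PhyloTree:
    """A uniform random binary topology on ``labels``.

    Sequential leaf addition: each new leaf attaches to an edge chosen
    uniformly among all current edges (pendant, internal, and the edge above
    the root), which makes every labelled topology equally likely.
    """
    rng = as_rng(rng)
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    if n < 3:
        raise ValueError("random_tree needs n >= 3")
    if not rooted:
        inner = _random_rooted_clades(labels[:-1], rng)
        t = PhyloTree(frozenset(labels[:-1]), inner, rooted=True, validate=False)
        return unroot_with(t, labels[-1])
    clades = _random_rooted_clades(labels, rng)
    return PhyloTree(frozenset(labels), clades, rooted=True, validate=False)


def _random_rooted_clades(labels: Sequence[str], rng) -> frozenset:
    clades: set = set()
    for i in range(2, len(labels)):
        x = labels[i]
        prevset = frozenset(labels[:i])
        edges: list = [None]  # the edge above the root
        edges += [frozenset({y}) for y in labels[:i]]
        edges += sorted(clades, key=lambda c: (len(c), sorted(c)))
        g = edges[int(rng.integers(len(edges)))]
        if g is None:
            clades.add(prevset)
        else:
            clades = {(c | {x}) if g < c else c for c in clades}
            clades.add(g | {x})
    return frozenset(clades)


def collapse_edges(t: PhyloTree, q: float, rng) -> PhyloTree:
    """Retain each internal edge independently with probability q.

    Models imperfect resolution of an estimated gene tree: q=1 leaves the
    tree untouched, q=0 collapses it to a star.  Pendant edges are never
    contracted (contracting one has no topological meaning).
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    rng = as_rng(rng)
    if q == 1 or not t.groups:
        return t
    keep = rng.random(len(t.groups)) < q
    groups = {g for g, k in zip(sorted(t.groups, key=_group_key), keep) if k}
    return PhyloTree(t.leaves, groups, rooted=t.rooted, validate=False)


def _group_key(g):
    if g and isinstance(next(iter(g)), frozenset):  # split
        return tuple(sorted(tuple(sorted(s)) for s in g))
    return tuple(sorted(g))
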