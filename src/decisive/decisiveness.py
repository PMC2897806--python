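"""Decisiveness of a taxon-coverage pattern.

A coverage pattern S = {Y_1..Y_k} is *decisive for a tree T* when the
induced subtrees T|Y_1..T|Y_k define T (T is the unique tree displaying all
of them), and *phylogenetically decisive for all trees* when this holds for
every binary tree on X.  The latter is characterized exactly by the
four-way partition condition: every partition of X into four nonempty
blocks must be crossed by some locus (a quadruple with one member per
block).  Around the exact test sit a cheap necessary screen (every triple
of taxa covered by some locus) and a sufficient one (a reference taxon
whose every quadruple is covered).

When a pattern is not decisive for all trees, two Monte Carlo summaries
quantify how close it comes over uniform random rooted trees:

* pi_D -- the probability that the pattern is decisive for a random tree;
* pi_d -- the expected fraction of a random tree's internal edges that the
  pattern distinguishes (averaged within a tree, then across trees).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from . import trees as _trees
from ._utils import GuardError, as_rng
from .coverage import (
    CoveragePattern,
    find_reference_taxa,
    triple_coverage,
)

#: default guard on exact four-way partition enumeration
FOUR_WAY_GUARD = 12
#: default guard on exhaustive enumeration over rooted trees
ENUM_GUARD = 9


def necessary_condition(pattern: CoveragePattern):
    """All-triples screen: returns (ok, triple_fraction, uncovered_witness)."""
    tc = triple_coverage(pattern)
    return tc.fraction == 1.0, tc.fraction, tc.uncovered_witness


def sufficient_condition(pattern: CoveragePattern):
    """Reference-taxon screen.

    Returns ``(ok, reference)``: ok is True when some reference taxon r has
    every quadruple {r,a,b,c} covered by a locus; None (not applicable) when
    the pattern has no reference taxon at all.
    """
    refs = find_reference_taxa(pattern)
    if not refs:
        return None, None
    for r in refs:
        reduced = CoveragePattern(
            [t for t in pattern.taxa if t != r],
            [y - {r} for y in pattern.loci],
            pattern.locus_names,
        )
        if reduced.n < 3:
            return True, r  # too few taxa for an uncovered triple to exist
        if triple_coverage(reduced).fraction == 1.0:
            return True, r
    return False, refs[0]


def four_way_condition(pattern: CoveragePattern, guard: int = FOUR_WAY_GUARD):
    """Exact decisiveness-for-all-trees test by four-block partition search.

    Enumerates set partitions of X into exactly four nonempty blocks
    (restricted-growth order) and requires some locus to intersect all four
    blocks of each.  Returns ``(ok, witness)`` where witness is the first
    violating partition (a tuple of four label tuples) when ok is False.
    """
    n = pattern.n
    if n < 4:
        raise ValueError("decisiveness concerns n >= 4 taxa")
    if n > guard:
        raise GuardError(
            f"four-way partition enumeration on n={n} exceeds the guard ({guard})"
        )
    masks = pattern.masks()
    taxa = pattern.taxa
    blocks = [0, 0, 0, 0]

    def witness_from(blocks):
        return tuple(
            tuple(t for i, t in enumerate(taxa) if (b >> i) & 1) for b in blocks
        )

    def rec(i: int, nblocks: int):
        if i == n:
            if nblocks < 4:
                return None
            b0, b1, b2, b3 = blocks
            for m in masks:
                if (m & b0) and (m & b1) and (m & b2) and (m & b3):
                    return None
            return witness_from(blocks)
        if nblocks + (n - i) < 4:
            return None
        bit = 1 << i
        for j in range(min(nblocks + 1, 4)):
            fresh = j == nblocks
            blocks[j] |= bit
            if fresh:
                nb = nblocks + 1
            else:
                nb = nblocks
            w = rec(i + 1, nb)
            blocks[j] &= ~bit
            if w is not None:
                return w
        return None

    w = rec(0, 0)
    return w is None, w


@dataclass(frozen=True)
class DecisivenessReport:
    """Outcome of the necessary / sufficient / exact condition cascade."""

    necessary_ok: bool
    triple_fraction: float
    triple_witness: Optional[tuple]
    sufficient_ok: Optional[bool]  # None: no reference taxon
    reference: Optional[str]
    exact_ok: Optional[bool]  # None: four-way enumeration guarded out
    partition_witness: Optional[tuple]
    verdict: str  # decisive_for_all | not_decisive_for_all | unknown


def check_decisiveness(
    pattern: CoveragePattern, guard: int = FOUR_WAY_GUARD
) -> DecisivenessReport:
    """Run the condition cascade and return a consistent verdict.

    The exact four-way test is skipped when the necessary screen already
    fails or the sufficient screen already succeeds; if it is infeasible
    (guard) and the screens are inconclusive the verdict is ``unknown``.
    """
    nec, frac, tw = necessary_condition(pattern)
    if not nec:
        return DecisivenessReport(
            nec, frac, tw, None, None, False, None, "not_decisive_for_all"
        )
    suf, ref = sufficient_condition(pattern)
    if suf:
        return DecisivenessReport(
            nec, frac, tw, suf, ref, True, None, "decisive_for_all"
        )
    try:
        ok, w = four_way_condition(pattern, guard=guard)
    except GuardError:
        return DecisivenessReport(nec, frac, tw, suf, ref, None, None, "unknown")
    verdict = "decisive_for_all" if ok else "not_decisive_for_all"
    return DecisivenessReport(nec, frac, tw, suf, ref, ok, w, verdict)


# ---------------------------------------------------------------------------
# decisiveness for a given tree


def decisive_for_tree(
    pattern: CoveragePattern,
    T: _trees.PhyloTree,
    guard: int = _trees.ENUM_GUARD_UNROOTED,
) -> bool:
    """Is the pattern decisive for the particular binary tree T?

    Rooted T: the induced subtrees define T iff every internal edge of T is
    distinguished by at least one locus, i.e. each edge's three non-root
    subtrees all contain a covered taxon.  Unrooted T: edge distinguishing
    is only necessary, so the check enumerates all binary trees on X and
    requires T to be the unique one displaying every induced subtree.
    """
    if T.leaves != frozenset(pattern.taxa):
        raise ValueError("tree leaves differ from the pattern's taxon set")
    if not T.is_binary:
        raise ValueError("decisiveness is defined for binary trees")
    if T.rooted:
        blocks = _trees.edge_blocks(T)
        loci = pattern.loci
        for e, bl in blocks.items():
            if not any(all(b & y for b in bl) for y in loci):
                return False
        return True
    inputs = [_trees.restrict(T, y) for y in pattern.loci if len(y) >= 1]
    if not inputs or frozenset().union(*(t.leaves for t in inputs)) != T.leaves:
        return False  # an uncovered taxon can never be placed
    ok, tree = _trees.defines(inputs, X=T.leaves, guard=guard)
    return ok and tree == T


# ---------------------------------------------------------------------------
# partial decisiveness


@dataclass(frozen=True)
class PartialDecisivenessEstimate:
    pi_D: float
    pi_d: float
    se_pi_D: float
    se_pi_d: float
    replicates: int
    seed: Optional[int]
    reference: str
    n_core: int  # taxa in the rooted problem (reference removed)

    def __post_init__(self):
        assert 0.0 <= self.pi_D <= self.pi_d <= 1.0


def _rooted_problem(pattern: CoveragePattern):
    """Root the pattern at its first reference taxon; error if none exists."""
    refs = find_reference_taxa(pattern)
    if not refs:
        raise ValueError(
            "partial decisiveness needs a reference taxon; apply "
            "coverage.reference_subset() first"
        )
    r = refs[0]
    core = [t for t in pattern.taxa if t != r]
    if len(core) < 3:
        raise ValueError("need at least 3 non-reference taxa")
    pos = {t: i for i, t in enumerate(core)}
    masks = [sum(1 << pos[t] for t in y if t != r) for y in pattern.loci]
    return r, core, pos, masks


def _tree_fraction(clades, leaves, pos, masks) -> float:
    """Fraction of the rooted tree's internal edges distinguished by >=1 locus."""
    t = _trees.PhyloTree(leaves, clades, rooted=True, validate=False)
    blocks = _trees.edge_blocks(t)
    hit = 0
    for e, bl in blocks.items():
        bm = [sum(1 << pos[x] for x in b) for b in bl]
        for m in masks:
            if all(m & b for b in bm):
                hit += 1
                break
    return hit / len(blocks)


def estimate_partial_decisiveness(
    pattern: CoveragePattern, replicates: int = 1000, seed=None
) -> PartialDecisivenessEstimate:
    """Monte Carlo pi_D and pi_d over uniform random rooted trees.

    The pattern must carry a reference taxon r, which serves as the root:
    trees are drawn uniformly on X - {r} and each locus acts through
    Y_i - {r}.  Standard errors are binomial for pi_D and the sample
    standard error of the per-tree fractions for pi_d.
    """
    if replicates < 1:
        raise ValueError("replicates >= 1 required")
    rng = as_rng(seed)
    r, core, pos, masks = _rooted_problem(pattern)
    leaves = frozenset(core)
    fracs = []
    for _ in range(replicates):
        clades = _trees._random_rooted_clades(core, rng)
        fracs.append(_tree_fraction(clades, leaves, pos, masks))
    R = replicates
    pi_d = sum(fracs) / R
    pi_D = sum(f == 1.0 for f in fracs) / R
    se_D = math.sqrt(pi_D * (1 - pi_D) / R)
    var_d = sum((f - pi_d) ** 2 for f in fracs) / max(R - 1, 1)
    se_d = math.sqrt(var_d / R)
    return PartialDecisivenessEstimate(
        pi_D, pi_d, se_D, se_d, R,
        seed if isinstance(seed, int) else None, r, len(core),
    )


def exact_partial_decisiveness(
    pattern: CoveragePattern, guard: int = ENUM_GUARD
) -> tuple[float, float]:
    """Exact pi_D and pi_d by enumerating all rooted trees on X - {r}."""
    r, core, pos, masks = _rooted_problem(pattern)
    if len(core) > guard:
        raise GuardError(
            f"exhaustive enumeration on n={len(core)} exceeds the guard ({guard})"
        )
    leaves = frozenset(core)
    total = 0
    sum_frac = 0.0
    full = 0
    for clades in _trees._rooted_clade_sets(core):
        f = _tree_fraction(clades, leaves, pos, masks)
        total += 1
        sum_frac += f
        full += f == 1.0
    return full / total, sum_frac / total
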