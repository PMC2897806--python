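"""Analytic bounds on the number of loci needed for decisiveness.

Two families of results are implemented.

*Fixed coverage.*  Counting arguments give necessary conditions: a
collection of trees defining an n-leaf tree must carry at least n-3
internal edges in total; locus sizes n_j must satisfy sum(n_j - 3) >= n - 3
for decisiveness for a given tree; and for decisiveness for *all* trees
every triple must be covered, whence sum C(n_j,3) >= C(n,3).  With a cap m
on locus size the latter yields the lower bound

    k >= ceil( C(n,3) / C(m,3) )  ~  (n/m)^3.

*Random coverage.*  If each taxon enters each locus independently with
probability p and each internal edge of an induced subtree survives with
probability q, then for any rooted n-taxon tree the probability that k loci
define it satisfies

    P >= 1 - E (1 - p^a q)^k,

with E the number of internal edges (n-2 rooted, n-3 unrooted) and a = 3
(rooted, or unrooted with an always-sampled reference taxon) or a = 4
(unrooted, uniform coverage).  Solving for a failure tolerance eps gives
the sufficient loci count; a matching extremal-tree argument (triples of
leaves hanging off a backbone, m = floor(n/3) independent cherry edges)
shows that below

    k <= ln(1 - (1-eps)^(1/m)) / ln(1 - p^3 q)

some trees are missed with probability > eps, an insufficiency threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb
from typing import Sequence, Union

from . import trees as _trees

MODELS = ("rooted_UC", "unrooted_UC1", "unrooted_UC")
_MODEL_ALIASES = {
    "rooted": "rooted_UC",
    "uc1": "unrooted_UC1",
    "unrooted": "unrooted_UC",
    "rooted_uc": "rooted_UC",
    "unrooted_uc1": "unrooted_UC1",
    "unrooted_uc": "unrooted_UC",
}


def _canon_model(model: str) -> str:
    m = _MODEL_ALIASES.get(model.lower(), model)
    if m not in MODELS:
        raise ValueError(f"unknown coverage model {model!r}; expected one of {MODELS}")
    return m


@dataclass(frozen=True)
class BoundSpec:
    """Parameters for the random-coverage loci bounds.

    n: taxon count; p: per-taxon inclusion probability; q: edge-retention
    probability of the resolution model; epsilon: tolerated failure
    probability; model: which tree/coverage regime sets the exponent on p
    and the internal-edge count.
    """

    n: int
    p: float
    q: float = 1.0
    epsilon: float = 0.05
    model: str = "rooted_UC"

    def __post_init__(self):
        object.__setattr__(self, "model", _canon_model(self.model))
        if self.n < 4:
            raise ValueError("n >= 4 required")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")

    @property
    def internal_edges(self) -> int:
        """n-2 for a rooted n-taxon tree, n-3 for an unrooted one."""
        return self.n - 2 if self.model == "rooted_UC" else self.n - 3

    @property
    def exponent(self) -> int:
        """Exponent a on p: 3 with a root/reference taxon, 4 without."""
        return 4 if self.model == "unrooted_UC" else 3


# ---------------------------------------------------------------------------
# fixed-pattern counting bounds


@dataclass(frozen=True)
class CountCheck:
    ok: bool
    total: int
    required: int
    #: how far short the total falls when not ok
    deficit: int = 0
    note: str = ""


def defining_edge_check(
    input_trees: Sequence[Union[_trees.PhyloTree, int]], n: int
) -> CountCheck:
    """Necessary condition to define an n-leaf tree: >= n-3 internal edges.

    Accepts trees or plain internal-edge counts.
    """
    total = sum(
        len(t.internal_edges) if isinstance(t, _trees.PhyloTree) else int(t)
        for t in input_trees
    )
    required = n - 3
    ok = total >= required
    return CountCheck(ok, total, required, max(required - total, 0))


def decisive_given_tree_check(sizes: Sequence[int], n: int) -> CountCheck:
    """Necessary (not sufficient) size condition: sum max(n_j-3,0) >= n-3.

    The bound is not tight: e.g. certain nine-leaf trees cannot be defined
    by any two six-leaf subtrees although 3+3 >= 6.
    """
    total = sum(max(s - 3, 0) for s in sizes)
    required = n - 3
    return CountCheck(
        total >= required, total, required, max(required - total, 0),
        note="necessary only; the bound is not tight",
    )


def loci_lower_bound_given_tree(n: int, m: int) -> int:
    """ceil((n-3)/(m-3)) loci of size <= m to be decisive for a given tree."""
    if m < 4:
        raise ValueError("m >= 4 required")
    return -((-(n - 3)) // (m - 3))


def triple_count_check(sizes: Sequence[int], n: int) -> CountCheck:
    """Triple-count condition for decisiveness for all trees.

    Every 3-subset of X must lie in some locus, so sum C(n_j,3) >= C(n,3).
    Exact integer arithmetic.
    """
    total = sum(comb(s, 3) for s in sizes)
    required = comb(n, 3)
    return CountCheck(total >= required, total, required, max(required - total, 0))


@dataclass(frozen=True)
class LociLowerBound:
    k_min: int  # ceil(C(n,3) / C(m,3)), exact integers
    k_ratio: int  # ceil((n/m)^3), the coarse 1/f^3 form
    n: int
    m: int


def min_loci_all_trees(n: int, m: int) -> LociLowerBound:
    """Lower bound on loci of size <= m for decisiveness for all trees.

    Reports the exact binomial-ratio bound and its (n/m)^3 approximation.
    """
    if not 4 <= m <= n:
        raise ValueError("need 4 <= m <= n")
    k_min = -((-comb(n, 3)) // comb(m, 3))
    k_ratio = math.ceil((n / m) ** 3)
    return LociLowerBound(k_min, k_ratio, n, m)


# ---------------------------------------------------------------------------
# random-coverage bounds


def define_probability_bound(spec: BoundSpec, k: int) -> float:
    """Lower bound on P(k random loci define the tree): 1 - E(1-p^a q)^k."""
    if k < 1:
        raise ValueError("k >= 1 required")
    x = spec.p ** spec.exponent * spec.q
    return max(0.0, 1.0 - spec.internal_edges * (1.0 - x) ** k)


def sufficient_loci(spec: BoundSpec) -> int:
    """Smallest k with E (1-p^a q)^k <= epsilon, guaranteeing P >= 1-eps."""
    x = spec.p ** spec.exponent * spec.q
    if x <= 0:
        raise ValueError("p and q must be positive: no finite k suffices")
    E, eps = spec.internal_edges, spec.epsilon
    if x >= 1 or E <= eps:
        return 1
    k = math.ceil(math.log(E / eps) / (-math.log(1.0 - x)))
    k = max(k, 1)
    while E * (1.0 - x) ** k > eps:  # guard the float ceiling
        k += 1
    while k > 1 and E * (1.0 - x) ** (k - 1) <= eps:
        k -= 1
    return k


def insufficient_loci(spec: BoundSpec) -> int:
    """Largest k still insufficient for some trees.

    On the extremal backbone-of-triples tree with m = floor(n/3) independent
    cherry edges, P(defined) <= (1 - (1-p^3 q)^k)^m; the returned k is the
    largest for which that stays below 1 - epsilon.  The exponent is 3 in
    every model (the extremal argument is rooted).
    """
    x = spec.p ** 3 * spec.q
    if x <= 0:
        raise ValueError("p and q must be positive")
    m = spec.n // 3
    if m < 1:
        raise ValueError("n too small")
    eps = spec.epsilon
    if x >= 1:
        return 0
    t = 1.0 - (1.0 - eps) ** (1.0 / m)
    k = math.floor(math.log(t) / math.log(1.0 - x))
    k = max(k, 0)
    while k > 0 and (1.0 - (1.0 - x) ** k) ** m >= 1.0 - eps:
        k -= 1
    while (1.0 - (1.0 - x) ** (k + 1)) ** m < 1.0 - eps:
        k += 1
    return k
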