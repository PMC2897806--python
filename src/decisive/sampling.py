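"""Random taxon-coverage generation and Monte Carlo define-probability.

The samplers implement the random-coverage regimes behind the analytic loci
bounds: uniform coverage (UC; every taxon enters every locus independently
with probability p), uniform-plus-reference (UC1; one taxon is always
sampled), and clade-variable coverage (VC; probability p inside a focal
clade, a smaller p' outside).  The Monte Carlo estimator draws coverage
patterns, applies the edge-retention resolution model, and measures how
often the collapsed induced subtrees pin down the target tree -- the
empirical counterpart of the analytic probability bound.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

import numpy as np

from . import trees as _trees
from ._utils import GuardError, as_rng
from .coverage import CoveragePattern

#: guard for brute-force unrooted define checks inside the MC loop
MC_UNROOTED_GUARD = 8


@dataclass(frozen=True)
class CoverageSampler:
    """Specification of a random coverage model over k loci."""

    model: str = "UC"  # UC | UC1 | VC
    p: float = 0.5
    k: int = 1
    reference: Optional[str] = None  # UC1: taxon sampled with probability 1
    clade: Optional[frozenset] = None  # VC: the well-covered clade
    p_out: Optional[float] = None  # VC: probability outside the clade (< p)

    def __post_init__(self):
        if self.model not in ("UC", "UC1", "VC"):
            raise ValueError("model must be UC, UC1 or VC")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k >= 1 required")
        if self.model == "VC":
            if self.clade is None or self.p_out is None:
                raise ValueError("VC needs a clade and p_out")
            if not 0 <= self.p_out < self.p:
                raise ValueError("VC requires 0 <= p_out < p")


def sample_coverage(sampler: CoverageSampler, taxa: Sequence[str], rng) -> CoveragePattern:
    """Draw one coverage pattern: k independent loci over ``taxa``.

    Empty loci are retained (they carry no phylogenetic content but arise
    naturally under sparse sampling).
    """
    rng = as_rng(rng)
    taxa = [str(t) for t in taxa]
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    probs = np.full(len(taxa), sampler.p)
    if sampler.model == "UC1":
        ref = sampler.reference if sampler.reference is not None else taxa[0]
        if ref not in taxa:
            raise ValueError(f"reference taxon {ref!r} not among the taxa")
        probs[taxa.index(ref)] = 1.0
    elif sampler.model == "VC":
        clade = frozenset(str(t) for t in sampler.clade)
        if not clade <= set(taxa):
            raise ValueError("VC clade is not a subset of the taxa")
        probs = np.where([t in clade for t in taxa], sampler.p, sampler.p_out)
    incl = rng.random((sampler.k, len(taxa))) < probs
    loci = [frozenset(t for t, keep in zip(taxa, row) if keep) for row in incl]
    return CoveragePattern(taxa, loci)


def monte_carlo_define_probability(
    T: _trees.PhyloTree,
    p: float,
    q: float,
    k: int,
    reps: int,
    rng,
    model: str = "UC",
    reference: Optional[str] = None,
) -> tuple[float, float]:
    """Estimate P(E_k(T)): k random loci, collapsed at rate 1-q, define T.

    Rooted T under UC: an internal edge is distinguished by a locus when
    the locus hits all three non-root subtrees at the edge and the matching
    induced edge survives collapse; T is defined iff every edge is
    distinguished by some locus.  Unrooted T under UC1 reduces exactly to
    the rooted case by rooting at the always-sampled reference taxon.
    Unrooted T under UC falls back to brute-force uniqueness per replicate
    (guarded).  Returns (estimate, binomial standard error).
    """
    rng = as_rng(rng)
    if reps < 1:
        raise ValueError("reps >= 1 required")
    if not 0 <= p <= 1 or not 0 <= q <= 1:
        raise ValueError("p and q must be in [0, 1]")
    if not T.is_binary:
        raise ValueError("T must be binary")
    if not T.rooted and model == "UC1":
        ref = reference if reference is not None else min(T.leaves)
        return monte_carlo_define_probability(
            _trees.root_at(T, ref), p, q, k, reps, rng, model="UC"
        )
    if not T.rooted:
        return _mc_unrooted_uc(T, p, q, k, reps, rng)

    leaves = sorted(T.leaves)
    pos = {t: i for i, t in enumerate(leaves)}
    blocks = _trees.edge_blocks(T)
    edges = sorted(blocks, key=lambda c: (len(c), sorted(c)))
    block_idx = [
        [np.fromiter((pos[x] for x in b), dtype=int) for b in blocks[e]]
        for e in edges
    ]
    E = len(edges)
    hits = 0
    for _ in range(reps):
        incl = rng.random((k, len(leaves))) < p
        retain = rng.random((k, E)) < q if q < 1 else np.ones((k, E), bool)
        ok = True
        for ei, bl in enumerate(block_idx):
            cond = retain[:, ei]
            for idx in bl:
                cond = cond & incl[:, idx].any(axis=1)
                if not cond.any():
                    break
            if not cond.any():
                ok = False
                break
        hits += ok
    est = hits / reps
    return est, sqrt(est * (1 - est) / reps)


def _mc_unrooted_uc(T, p, q, k, reps, rng):
    if T.n > MC_UNROOTED_GUARD:
        raise GuardError(
            f"unrooted UC Monte Carlo requires brute-force uniqueness; "
            f"n={T.n} exceeds the guard ({MC_UNROOTED_GUARD})"
        )
    taxa = sorted(T.leaves)
    hits = 0
    for _ in range(reps):
        incl = rng.random((k, len(taxa))) < p
        inputs = []
        for row in incl:
            y = frozenset(t for t, keep in zip(taxa, row) if keep)
            if not y:
                continue
            sub = _trees.restrict(T, y)
            inputs.append(_trees.collapse_edges(sub, q, rng))
        if not inputs or frozenset().union(*(t.leaves for t in inputs)) != T.leaves:
            continue
        ok, tree = _trees.defines(inputs, X=T.leaves, guard=MC_UNROOTED_GUARD)
        hits += ok and tree == T
    est = hits / reps
    return est, sqrt(est * (1 - est) / reps)


def worst_case_tree(n: int, labels: Optional[Sequence[str]] = None) -> _trees.PhyloTree:
    """The extremal rooted tree behind the insufficiency threshold.

    A backbone caterpillar on m = floor(n/3) units, each unit a 3-leaf
    subtree (cherry plus leaf).  The m cherry edges each see single-leaf
    subtrees on all three non-root sides, so their chances of being
    distinguished are independent and individually minimal -- the tree a
    random sampling design is most likely to miss.  Leftover taxa (n mod 3)
    are attached as a deterministic unit under a new root.
    """
    if n < 9:
        raise ValueError("worst_case_tree needs n >= 9 (at least 3 units)")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError("need n unique labels")
    m, r = divmod(n, 3)
    clades = set()
    units = []
    for i in range(m):
        a, b, c = labels[3 * i: 3 * i + 3]
        clades.add(frozenset({a, b}))  # the cherry: all three side blocks are leaves
        clades.add(frozenset({a, b, c}))
        units.append(frozenset({a, b, c}))
    cum = units[0]
    backbone_top = frozenset().union(*units)
    for u in units[1:]:
        cum = cum | u
        if cum != backbone_top or r > 0:
            clades.add(cum)
    rest = labels[3 * m:]
    if r == 2:
        clades.add(frozenset(rest))
    return _trees.PhyloTree(frozenset(labels), clades, rooted=True, validate=False)
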