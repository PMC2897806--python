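import logging
import random

import pytest

from decisive import CoveragePattern

# the "no locus" warnings are expected noise under random sparse sampling
logging.getLogger("decisive.coverage").setLevel(logging.ERROR)


@pytest.fixture
def complete5():
    """Complete coverage: one locus with all five taxa (plus a duplicate)."""
    return CoveragePattern(list("ABCDE"), [set("ABCDE"), set("ABCDE")])


@pytest.fixture
def abcd_abcf():
    """The pathological two-block pattern {A,B,C,D} / {A,B,C,F}."""
    return CoveragePattern(list("ABCDF"), [set("ABCD"), set("ABCF")])


@pytest.fixture
def ref_quads6():
    """All quadruples through reference taxon A on six taxa (sufficient)."""
    from itertools import combinations

    loci = [frozenset({"A"}) | frozenset(c) for c in combinations("BCDEF", 3)]
    return CoveragePattern(list("ABCDEF"), loci)


@pytest.fixture
def og_pattern_6_of_15():
    """Outgroup-rooted pattern decisive for exactly 6 of the 15 rooted
    four-taxon trees (two overlapping quadruple loci through OG)."""
    return CoveragePattern(
        ["OG", "A", "B", "C", "D"],
        [frozenset({"OG", "A", "B", "C"}), frozenset({"OG", "A", "B", "D"})],
    )


def random_pattern(rng: random.Random, n: int, k: int, p: float) -> CoveragePattern:
    """A random coverage pattern for property tests (plain Bernoulli cells)."""
    taxa = [chr(65 + i) for i in range(n)]
    loci = [frozenset(t for t in taxa if rng.random() < p) for _ in range(k)]
    return CoveragePattern(taxa, loci)
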