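import itertools
import random

import numpy as np
import pytest

from decisive import (
    GuardError,
    PhyloTree,
    collapse_edges,
    count_trees,
    defines,
    displays,
    distinguished_edges,
    enumerate_trees,
    parse_newick,
    random_tree,
    restrict,
    root_at,
    unroot_with,
    write_newick,
)
from decisive import trees as tr

CATERPILLAR = "(((A,B),C),D);"


def fs(*xs):
    return frozenset(xs)


class TestNewick:
    def test_quartet_unrooted(self):
        t = parse_newick("((A,B),(C,D));", rooted=False)
        assert not t.rooted
        assert t.groups == {frozenset({fs("A", "B"), fs("C", "D")})}

    def test_rooted_caterpillar_two_internal_edges(self):
        t = parse_newick(CATERPILLAR)
        assert t.rooted  # degree-2 root implies rooted
        assert t.groups == {fs("A", "B"), fs("A", "B", "C")}

    def test_basal_trifurcation_reads_unrooted(self):
        t = parse_newick("(A,B,(C,D));")
        assert not t.rooted

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B),(C,D);")

    def test_duplicate_labels_raise(self):
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            parse_newick("((A,A),B);")

    @pytest.mark.parametrize("rooted", [True, False])
    def test_round_trip_random_trees(self, rooted):
        labels = [f"t{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = random_tree(labels, rooted=rooted, rng=rng)
            assert parse_newick(write_newick(t), rooted=rooted) == t

    def test_branch_lengths_ignored(self):
        a = parse_newick("(((A:1,B:2):0.5,C:1):2,D:1);")
        assert a == parse_newick(CATERPILLAR)


class TestRestrictDisplay:
    def test_restrict_to_all_leaves_is_identity(self):
        t = parse_newick(CATERPILLAR)
        assert restrict(t, t.leaves) == t

    def test_restrict_caterpillar(self):
        t = parse_newick(CATERPILLAR)
        assert restrict(t, {"A", "C", "D"}) == parse_newick("((A,C),D);")

    def test_restrict_quartet_to_triple_is_star(self):
        q = parse_newick("((A,B),(C,D));", rooted=False)
        r = restrict(q, {"A", "B", "C"})
        assert r.groups == frozenset()

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="not in tree"):
            restrict(parse_newick(CATERPILLAR), {"A", "Z"})

    def test_displays_own_restrictions(self):
        rng = np.random.default_rng(1)
        labels = [f"t{i}" for i in range(7)]
        pyrng = random.Random(2)
        for rooted in (True, False):
            for _ in range(20):
                t = random_tree(labels, rooted=rooted, rng=rng)
                y = {x for x in labels if pyrng.random() < 0.6}
                if len(y) >= 1:
                    assert displays(t, restrict(t, y))

    def test_conflicting_quartet_not_displayed(self):
        t = parse_newick("((A,B),(C,D));", rooted=False)
        other = parse_newick("((A,C),(B,D));", rooted=False)
        assert not displays(t, other)

    def test_star_displayed_by_any_resolution(self):
        t = parse_newick("(((A,B),(C,D)),(E,F));", rooted=False)
        star = PhyloTree(fs("A", "C", "E", "F"), (), rooted=False)
        assert displays(t, star)


class TestDistinguishedEdges:
    def test_full_leaf_set_distinguishes_everything(self):
        t = parse_newick(CATERPILLAR)
        assert distinguished_edges(t, t.leaves) == t.groups

    def test_rooted_caterpillar_partial(self):
        t = parse_newick(CATERPILLAR)
        # {A,B,C} hits the three subtrees of the cherry edge ({A},{B},{C})
        # but leaves the clade-{A,B,C} edge without a leaf in its sibling {D}
        assert distinguished_edges(t, {"A", "B", "C"}) == {fs("A", "B")}

    def test_too_few_leaves_distinguish_nothing(self):
        t = parse_newick(CATERPILLAR)
        assert distinguished_edges(t, {"A", "B"}) == frozenset()

    def test_nonbinary_rejected(self):
        t = parse_newick("((A,B,C),D,E);")
        with pytest.raises(ValueError, match="binary"):
            distinguished_edges(t, t.leaves)

    @staticmethod
    def _displayed_triples(t):
        out = set()
        for trip in itertools.combinations(sorted(t.leaves), 3):
            r = restrict(t, trip)
            for g in r.groups:
                (c,) = tuple(r.leaves - g)
                out.add((frozenset(g), c))
        return out

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_direct_triple_definition(self, seed):
        """An edge is distinguished iff some rooted triple from Y is displayed
        by both T and T|Y but not by T with that edge collapsed."""
        pyrng = random.Random(seed)
        n = pyrng.choice([5, 6, 7])
        labels = [chr(65 + i) for i in range(n)]
        T = random_tree(labels, rooted=True, rng=np.random.default_rng(seed))
        Y = frozenset(x for x in labels if pyrng.random() < 0.7)
        if len(Y) < 3:
            Y = frozenset(labels[:3])
        trips_T = self._displayed_triples(T)
        trips_tY = self._displayed_triples(restrict(T, Y))
        expected = set()
        for e in T.groups:
            Te = PhyloTree(T.leaves, T.groups - {e}, rooted=True)
            trips_Te = self._displayed_triples(Te)
            if any(x in trips_T and x not in trips_Te for x in trips_tY):
                expected.add(e)
        assert distinguished_edges(T, Y) == frozenset(expected)


class TestDefines:
    def test_two_quartets_define_five_leaf_caterpillar(self):
        q1 = parse_newick("((A,B),(C,D));", rooted=False)
        q2 = parse_newick("((B,C),(D,E));", rooted=False)
        ok, T = defines([q1, q2])
        assert ok and T == parse_newick("(A,B,(C,(D,E)));")

    def test_induced_subtrees_need_not_define_their_source(self):
        # same coverage, two trees: the induced subtrees define one of them
        # but not the other (uncovered quartets leave room for alternatives)
        pat_loci = [fs("A", "B", "C", "D"), fs("A", "B", "C", "E")]
        good = parse_newick("(A,(B,(C,E)),D);")
        bad = parse_newick("(A,B,(C,(D,E)));")
        ok_good, t = defines([restrict(good, y) for y in pat_loci], X=good.leaves)
        assert ok_good and t == good
        ok_bad, _ = defines([restrict(bad, y) for y in pat_loci], X=bad.leaves)
        assert not ok_bad

    def test_single_partial_input_never_defines(self):
        t = parse_newick("((A,B),(C,D));", rooted=False)
        with pytest.raises(ValueError, match="union"):
            defines([t], X=fs("A", "B", "C", "D", "E"))

    def test_guard_on_large_unrooted_instances(self):
        labels = [f"t{i}" for i in range(12)]
        t = random_tree(labels, rooted=False, rng=np.random.default_rng(0))
        with pytest.raises(GuardError):
            defines([t], X=t.leaves)

    @pytest.mark.parametrize("seed", range(15))
    def test_rooted_criterion_agrees_with_enumeration(self, seed):
        """BUILD + display/distinguish must equal brute-force uniqueness."""
        pyrng = random.Random(seed)
        n = pyrng.choice([4, 5, 6, 7])
        labels = [chr(65 + i) for i in range(n)]
        T = random_tree(labels, rooted=True, rng=np.random.default_rng(seed))
        g = np.random.default_rng(seed + 100)
        inputs = []
        for _ in range(pyrng.randint(1, 5)):
            y = frozenset(x for x in labels if pyrng.random() < 0.7)
            if y:
                sub = restrict(T, y)
                if pyrng.random() < 0.3:
                    sub = collapse_edges(sub, 0.7, g)
                inputs.append(sub)
        if not inputs:
            return
        X = frozenset().union(*(t.leaves for t in inputs))
        if len(X) < 2:
            return
        got, got_tree = defines(inputs, X=X)
        found, count = None, 0
        for cand in enumerate_trees(sorted(X), rooted=True):
            if all(displays(cand, t) for t in inputs):
                count += 1
                found = cand
        assert got == (count == 1)
        if got:
            assert got_tree == found


class TestEnumeration:
    def test_fifteen_rooted_trees_on_four_taxa(self):
        trees = list(enumerate_trees("ABCD", rooted=True))
        assert len(trees) == 15
        assert len(set(trees)) == 15

    def test_three_unrooted_quartets(self):
        assert sum(1 for _ in enumerate_trees("ABCD", rooted=False)) == 3

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_rooted_counts_match_double_factorial(self, n):
        labels = [chr(65 + i) for i in range(n)]
        trees = list(enumerate_trees(labels, rooted=True))
        assert len(trees) == len(set(trees)) == count_trees(n, rooted=True)
        assert all(t.is_binary for t in trees)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_unrooted_counts_match_double_factorial(self, n):
        labels = [chr(65 + i) for i in range(n)]
        trees = list(enumerate_trees(labels, rooted=False))
        assert len(trees) == len(set(trees)) == count_trees(n, rooted=False)

    def test_guard(self):
        with pytest.raises(GuardError):
            list(enumerate_trees([f"t{i}" for i in range(11)], rooted=True))


class TestRandomTree:
    def test_deterministic_under_seed(self):
        labels = [f"t{i}" for i in range(10)]
        a = [random_tree(labels, True, np.random.default_rng(5)) for _ in range(3)]
        b = [random_tree(labels, True, np.random.default_rng(5)) for _ in range(3)]
        assert a == b

    def test_three_leaf_symmetry(self):
        rng = np.random.default_rng(8)
        counts = {}
        for _ in range(3000):
            t = random_tree("ABC", rooted=True, rng=rng)
            counts[t.groups] = counts.get(t.groups, 0) + 1
        assert len(counts) == 3
        assert all(abs(c / 3000 - 1 / 3) < 0.05 for c in counts.values())

    def test_all_topologies_binary(self):
        rng = np.random.default_rng(9)
        for rooted in (True, False):
            for _ in range(20):
                assert random_tree("ABCDEF", rooted, rng).is_binary


class TestRootingConversions:
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip(self, seed):
        labels = [f"t{i}" for i in range(7)]
        t = random_tree(labels, rooted=True, rng=np.random.default_rng(seed))
        assert root_at(unroot_with(t, "out"), "out") == t

    def test_rooted_n_has_unrooted_n_plus_1_edge_count(self):
        t = random_tree([f"t{i}" for i in range(6)], True, np.random.default_rng(1))
        u = unroot_with(t, "out")
        assert len(u.internal_edges) == len(t.internal_edges) == 4


class TestCollapse:
    def test_q_one_is_identity(self):
        t = parse_newick(CATERPILLAR)
        assert collapse_edges(t, 1.0, np.random.default_rng(0)) == t

    def test_q_zero_is_star(self):
        t = parse_newick(CATERPILLAR)
        assert collapse_edges(t, 0.0, np.random.default_rng(0)).groups == frozenset()

    def test_mean_retained_edges_binomial(self):
        t = random_tree([f"t{i}" for i in range(6)], True, np.random.default_rng(2))
        assert len(t.groups) == 4
        rng = np.random.default_rng(3)
        total = sum(
            len(collapse_edges(t, 0.5, rng).groups) for _ in range(10_000)
        )
        mean = total / 10_000
        # Binomial(4, 0.5): sd of the mean = 1/sqrt(10000)
        assert abs(mean - 2.0) < 0.05
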