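# Methods

## Scope and model

`decisive` treats missing data at the whole-sequence level: a coverage
pattern S = {Y_1..Y_k} records which taxa have *any* data at each locus,
and all questions are purely topological — whether the subtrees a true
tree would induce on the covered taxon sets suffice to reconstruct it.
Sequence content, branch lengths, gene-tree conflict and reconstruction
error are deliberately outside the model; the package isolates what the
coverage pattern alone can or cannot support.

Trees are stored as their clade sets (rooted) or split sets (unrooted).
These systems are in bijection with topologies, so restriction (T|Y),
display, and edge identity reduce to set algebra, and internal edges are
canonically keyed by the clade or split they induce — directly comparable
across trees and operations.  A rooted tree on n leaves is interconvertible
with an unrooted tree on n+1 leaves by adding/removing a root leaf, and all
rooted machinery exploits this.

## Decisiveness tests

For a fixed pattern the package runs a cascade:

* **Necessary.**  Every 3-subset of X must lie inside some locus.  Counted
  exactly with per-locus bitmasks (union over loci, no double counting);
  the fraction of covered triples is reported as a graded diagnostic, and
  a first uncovered triple is returned as a certificate.
* **Sufficient.**  If some reference taxon r (present in every locus) has
  every quadruple {r,a,b,c} inside some locus, the pattern is decisive for
  all trees.  Implemented as the triple condition on the pattern with r
  removed.
* **Exact.**  Decisiveness for all trees holds iff every partition of X
  into four nonempty blocks is crossed by some locus (a quadruple with one
  member in each block).  Partitions are enumerated in restricted-growth
  order with early exit; on failure the first violating partition is
  returned, a checkable certificate.  The enumeration is guarded (default
  n <= 12, overridable); beyond the guard the verdict falls back to the
  screens: necessary fails -> not decisive, sufficient holds -> decisive,
  otherwise unknown.

For a *given* binary rooted tree T, decisiveness is characterized by edge
distinguishing: each internal edge (clade C with child subtrees C1, C2 and
sibling subtree D) must have some locus meeting C1, C2 and D.  For
partially resolved inputs an edge additionally counts only if its image
edge survives in the input — this is exactly when some rooted triple from
the input separates across the edge.  For unrooted trees distinguishing is
necessary but not sufficient, so the package decides "defines" by
enumeration over all binary trees (guarded, default n <= 10).  The rooted
path of `defines` assembles a candidate supertree with the BUILD algorithm
from the inputs' resolved triples; a non-binary BUILD tree already implies
non-uniqueness (the BUILD tree and any refinement both display the
inputs), and a binary one is checked by the display + all-edges-
distinguished criterion.

## Partial decisiveness

When a pattern is not decisive for all trees, two summaries are estimated
over uniform random rooted trees:

* Pi_D — probability the pattern is decisive for a random tree;
* Pi_d — expected fraction of a random tree's internal edges distinguished
  by at least one locus (averaged within a tree, then across trees; the
  per-tree-then-across-trees order makes Pi_d >= Pi_D an identity, since a
  fraction is at least the indicator of its being 1).

Estimation is restricted to the rooted case (where the edge criterion is
exact): the pattern must have a reference taxon r, which is removed and
used as the root; callers without one first apply `reference_subset`,
which keeps the loci of the best-covered taxon (ties broken by declared
taxa order, deterministically) and drops taxa left without data.  The
default is 1000 replicate trees; the API requires an explicit seed and the
CLI defaults and echoes one.  Standard errors are binomial for Pi_D and
the sample standard error of per-tree fractions for Pi_d.  For n <= 9
non-reference taxa, `exact_partial_decisiveness` enumerates all (2n-3)!!
rooted trees instead; the Monte Carlo path is tested against it.

Random topologies are generated by sequential leaf addition with the
attachment edge chosen uniformly among all current edges (including the
edge above the root), which is uniform over labelled topologies; the
suite checks this by chi-square against the 15 rooted four-taxon trees.

## Random-coverage bounds

Under uniform coverage (each taxon in each locus independently with
probability p; optionally one reference taxon always present) and the
q-resolution model (each internal edge of an induced subtree retained
independently with probability q), the probability that k loci define a
fixed tree satisfies

    P >= 1 - E (1 - p^a q)^k,

with E the internal-edge count (n-2 rooted, n-3 unrooted) and a = 3 when a
root/reference taxon is available, a = 4 for unrooted uniform coverage.
The sufficient loci count is the smallest integer k with
E (1-p^a q)^k <= eps (a ceiling of the log expression, then verified
against the inequality directly to absorb float rounding).  Conversely, on
the extremal tree — a backbone caterpillar whose m = floor(n/3) leaves are
replaced by 3-leaf subtrees, so the m cherry edges have single-leaf side
subtrees and are distinguished independently with the minimal probability
p^3 q per locus — the define probability is at most
(1 - (1-p^3 q)^k)^m, and the insufficiency threshold is the largest k
keeping that below 1-eps (floor, verified the same way).  The exponent
stays 3 in every model for the threshold, following the extremal
construction.  Leftover taxa (n mod 3) are attached as a deterministic
caterpillar under a new root; this does not touch the cherry edges'
independence.

The rounding conventions (ceiling for sufficiency, floor for
insufficiency) are applied uniformly; no adjustment is made for inputs
quoted at limited precision, so configurations whose published densities
were rounded can differ by one locus in the last place.

Monte Carlo validation (`sampling.monte_carlo_define_probability`) samples
coverage and retention directly.  In the rooted fast path an edge is
distinguished by locus i iff the locus meets the edge's three non-root
blocks and that edge's retention coin succeeds; distinct distinguishable
edges always map to distinct induced edges, so one independent coin per
(edge, locus) pair is exact.  Unrooted uniform coverage has no comparable
characterization and falls back to brute-force uniqueness per replicate
(guarded, n <= 8); unrooted coverage with a reference taxon reduces
exactly to the rooted case by rooting at the reference leaf, since rooting
at a shared leaf is a display- and uniqueness-preserving bijection.

No closed-form bound is offered for clade-variable coverage (VC);
the sampler supports it for Monte Carlo exploration only.

## Synthetic data

All fixtures are generated programmatically: canonical small patterns
(complete coverage; the {A,B,C,D}/{A,B,C,F} pathological pair; all
quadruples through a reference taxon; an outgroup pattern decisive for
exactly 6 of 15 rooted trees) plus uniform-coverage samples at stated n,
k, p, seed.  The generators emulate the random-coverage models above —
independent Bernoulli inclusion per cell — and therefore do *not* emulate
features of real supermatrices such as phylogenetically clustered
missingness, locus-size heterogeneity, or correlated library dropout.
Passing tests show the combinatorics and the estimators are correct under
the stated models, not that any real data set is decisive.

## Numerical and interface conventions

* Exact integer binomials everywhere in the counting bounds; doubles only
  inside logs for the loci-count formulas, with integer results verified
  against the defining inequality.
* Guards (exact four-way test n <= 12, tree enumeration n <= 9 rooted /
  10 unrooted, triple enumeration 5e7) raise a named `GuardError` rather
  than silently switching methods; all are overridable parameters.  The
  defaults keep the full test suite in the minutes range on one CPU; test
  problem sizes (enumeration oracles at n <= 7, Monte Carlo grids at
  n <= 8 with 300-800 replicates) were chosen the same way.
* Empty and sub-triple loci are retained throughout (they arise naturally
  under sparse sampling) but contribute no triples, quadruples or edges;
  density counts them in k.
* Pendant edges are never collapsed by the q-resolution model — only
  internal edges have a topological identity to lose.
* Matrix orientation is taxa-rows by loci-columns; `--transpose` accepts
  the other convention.  Round-tripping either text format preserves taxa
  order, locus order and membership exactly.
* Deterministic tie-breaks everywhere randomness is not wanted: reference
  taxon by declared order, Newick children sorted by smallest label, edge
  lists sorted by (size, labels) before seeded sampling.

## Limitations

* The exact all-trees test is exponential in n; beyond the guard only the
  necessary/sufficient screens apply and the verdict may be `unknown`.
* Pi_D / Pi_d are defined through a reference taxon; patterns without one
  are analyzed on their reference subset, which measures a sub-matrix, not
  the full pattern.
* Finding which loci to *add* to make a pattern decisive, identifying
  maximal decisive taxon subsets, and grove-style partial information are
  out of scope.
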