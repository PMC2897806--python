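"""Taxon-coverage patterns of multilocus data sets.

A coverage pattern records, for each locus in a supermatrix, the set of taxa
for which a sequence is present at all.  Coverage here is whole-sequence
presence/absence per locus, not per-site missingness within an alignment.
The pattern is the object whose combinatorics determine whether the induced
per-locus subtrees can single out one tree on the full taxon set.

Two plain-text notations are supported: a 0/1 matrix (rows = taxa, columns =
loci) and a sets file (one locus per line with its comma-separated taxa).
"""
from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from math import comb
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._utils import GuardError

log = logging.getLogger(__name__)

#: refuse exact triple enumeration beyond this many 3-subsets
DEFAULT_TRIPLE_GUARD = 50_000_000


class CoveragePattern:
    """The taxon set X together with one taxon subset per locus.

    Parameters
    ----------
    taxa
        Ordered, unique taxon labels (the label set X, n = len(taxa)).
    loci
        One taxon subset per locus (Y_1..Y_k).  Duplicates and empty sets
        are allowed; every member must belong to ``taxa``.
    locus_names
        Optional locus labels; defaults to L1..Lk.
    """

    __slots__ = ("taxa", "loci", "locus_names")

    def __init__(
        self,
        taxa: Sequence[str],
        loci: Iterable[Iterable[str]],
        locus_names: Optional[Sequence[str]] = None,
    ):
        taxa = tuple(str(t) for t in taxa)
        if len(taxa) == 0:
            raise ValueError("a coverage pattern needs at least one taxon")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels")
        universe = frozenset(taxa)
        loci = tuple(frozenset(str(t) for t in y) for y in loci)
        if len(loci) == 0:
            raise ValueError("a coverage pattern needs at least one locus")
        for j, y in enumerate(loci):
            extra = y - universe
            if extra:
                raise ValueError(
                    f"locus {j} contains labels not in the taxon set: {sorted(extra)}"
                )
        if locus_names is None:
            locus_names = tuple(f"L{j + 1}" for j in range(len(loci)))
        else:
            locus_names = tuple(str(s) for s in locus_names)
            if len(locus_names) != len(loci):
                raise ValueError("locus_names length mismatch")
        covered = set().union(*loci) if loci else set()
        for t in taxa:
            if t not in covered:
                log.warning("taxon %r occurs in no locus", t)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "locus_names", locus_names)

    def __setattr__(self, *a):  # immutable
        raise AttributeError("CoveragePattern is immutable")

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def k(self) -> int:
        return len(self.loci)

    def __eq__(self, other):
        return (
            isinstance(other, CoveragePattern)
            and self.taxa == other.taxa
            and self.loci == other.loci
            and self.locus_names == other.locus_names
        )

    def __hash__(self):
        return hash((self.taxa, self.loci))

    def __repr__(self):
        return f"CoveragePattern(n={self.n}, k={self.k})"

    def to_frame(self) -> pd.DataFrame:
        """0/1 presence matrix, taxa as rows, loci as columns."""
        data = {
            name: [int(t in y) for t in self.taxa]
            for name, y in zip(self.locus_names, self.loci)
        }
        return pd.DataFrame(data, index=list(self.taxa))

    def masks(self) -> list[int]:
        """Each locus as a bitmask over taxa order (bit i = taxa[i])."""
        pos = {t: i for i, t in enumerate(self.taxa)}
        return [sum(1 << pos[t] for t in y) for y in self.loci]


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if os.path.exists(s):
        with open(s) as fh:
            return fh.read()
    if "\n" in s or "," in s or "\t" in s:
        return s
    raise FileNotFoundError(source)


def _looks_like_matrix(text: str) -> bool:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        return False
    sep = "\t" if "\t" in lines[1] else ","
    cells = lines[1].split(sep)[1:]
    return bool(cells) and all(c.strip() in ("0", "1") for c in cells)


def read_coverage(source, format: Optional[str] = None) -> CoveragePattern:
    """Read a coverage pattern from a file path, text, or file object.

    ``format`` is ``"matrix"``, ``"sets"``, or ``None`` to sniff: a table
    whose data cells are all 0/1 is taken as a matrix.
    """
    text = _read_text(source)
    if format is None:
        format = "matrix" if _looks_like_matrix(text) else "sets"
    if format == "matrix":
        return _read_matrix(text)
    if format == "sets":
        return _read_sets(text)
    raise ValueError(f"unknown coverage format: {format!r}")


def _read_matrix(text: str) -> CoveragePattern:
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate taxon label(s): {dups}")
    bad = ~df.isin([0, 1]).to_numpy()
    if bad.any():
        r, c = [int(x[0]) for x in bad.nonzero()]
        raise ValueError(
            f"non-binary cell at taxon {df.index[r]!r}, locus {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    taxa = [str(t) for t in df.index]
    loci = [frozenset(df.index[df[col] == 1].astype(str)) for col in df.columns]
    return CoveragePattern(taxa, loci, [str(c) for c in df.columns])


def _read_sets(text: str) -> CoveragePattern:
    declared: Optional[list[str]] = None
    names: list[str] = []
    loci: list[list[str]] = []
    seen: list[str] = []  # taxa in order of first appearance
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip()[1:].strip()
            if body.lower().startswith("taxa:"):
                declared = [t.strip() for t in body[5:].split(",") if t.strip()]
            continue
        if "\t" in line:
            name, rest = line.split("\t", 1)
        elif ":" in line:
            name, rest = line.split(":", 1)
        else:
            raise ValueError(f"line {lineno}: expected 'name<TAB>taxa' or 'name: taxa'")
        members = [t.strip() for t in rest.split(",") if t.strip()]
        names.append(name.strip())
        loci.append(members)
        for t in members:
            if t not in seen:
                seen.append(t)
    if declared is not None:
        missing = set(seen) - set(declared)
        if missing:
            raise ValueError(
                f"taxa {sorted(missing)} appear in loci but not in the #taxa: header"
            )
        taxa = declared
    else:
        taxa = seen
    return CoveragePattern(taxa, loci, names)


def write_coverage(pattern: CoveragePattern, path=None, format: str = "matrix") -> str:
    """Serialize ``pattern``; returns the text and optionally writes ``path``."""
    if format == "matrix":
        text = pattern.to_frame().to_csv(index_label="taxon")
    elif format == "sets":
        lines = ["#taxa: " + ",".join(pattern.taxa)]
        order = {t: i for i, t in enumerate(pattern.taxa)}
        for name, y in zip(pattern.locus_names, pattern.loci):
            lines.append(name + "\t" + ",".join(sorted(y, key=order.__getitem__)))
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown coverage format: {format!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def coverage_density(pattern: CoveragePattern) -> float:
    """Fraction of filled cells in the taxa-by-loci matrix: sum|Y_i| / (n k)."""
    return sum(len(y) for y in pattern.loci) / (pattern.n * pattern.k)


@dataclass(frozen=True)
class TripleCoverage:
    covered: int
    total: int
    fraction: float
    #: one uncovered triple (taxa-order indices resolved to labels), or None
    uncovered_witness: Optional[tuple[str, str, str]]


def triple_coverage(
    pattern: CoveragePattern, guard: int = DEFAULT_TRIPLE_GUARD
) -> TripleCoverage:
    """Count the 3-subsets of X contained in at least one locus.

    Exact (no double counting): a triple is covered iff some Y_i contains it.
    Decisiveness for all trees requires every triple to be covered, so the
    fraction reported here is the cheap first screen of a pattern.
    """
    n = pattern.n
    if n < 3:
        raise ValueError("triple coverage needs n >= 3")
    total = comb(n, 3)
    if total > guard:
        raise GuardError(
            f"C({n},3) = {total} exceeds the triple-enumeration guard ({guard}); "
            "raise `guard` to force the computation"
        )
    masks = pattern.masks()
    covered = 0
    witness = None
    for i in range(n - 2):
        bi = 1 << i
        pair_masks = [m for m in masks if m & bi]
        for j in range(i + 1, n - 1):
            bj = 1 << j
            u = 0
            for m in pair_masks:
                if m & bj:
                    u |= m
            rest = u >> (j + 1)
            got = rest.bit_count()
            covered += got
            if witness is None and got < n - 1 - j:
                for l in range(j + 1, n):
                    if not (u >> l) & 1:
                        witness = (pattern.taxa[i], pattern.taxa[j], pattern.taxa[l])
                        break
    return TripleCoverage(covered, total, covered / total, witness)


def find_reference_taxa(pattern: CoveragePattern) -> list[str]:
    """Taxa present in every locus (the intersection of all Y_i), in taxa order."""
    common = frozenset.intersection(*pattern.loci)
    return [t for t in pattern.taxa if t in common]


def reference_subset(pattern: CoveragePattern) -> tuple[CoveragePattern, str]:
    """Prune the pattern down to the loci of its best-covered taxon.

    Picks the taxon present in the most loci (ties broken by taxa order),
    drops every locus lacking it, then drops taxa left with no data.  The
    chosen taxon is a reference taxon of the result, which makes the reduced
    pattern rootable for the partial-decisiveness estimators.
    """
    counts = {t: sum(t in y for y in pattern.loci) for t in pattern.taxa}
    ref = max(pattern.taxa, key=lambda t: counts[t])  # max is stable: first wins ties
    if counts[ref] == 0:
        raise ValueError("all loci are empty; no reference subset exists")
    kept = [
        (name, y)
        for name, y in zip(pattern.locus_names, pattern.loci)
        if ref in y
    ]
    kept_union = frozenset().union(*(y for _, y in kept))
    taxa = [t for t in pattern.taxa if t in kept_union]
    sub = CoveragePattern(taxa, [y for _, y in kept], [name for name, _ in kept])
    return sub, ref
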