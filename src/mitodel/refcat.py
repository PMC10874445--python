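"""Mitochondrial reference, deletion catalog, and breakpoint arithmetic.

Coordinates are 1-based and inclusive throughout. A deletion breakpoint is
named by the pair (b5, b3) where ``b5`` is the last retained base on the 5'
side of the junction and ``b3`` the first retained base on the 3' side, so
the number of deleted bases is ``b3 - b5 - 1``. Under this convention the
8471-13449 "common deletion" removes 4977 bp.

Because large mtDNA deletions typically arise between short direct repeats,
the same deleted molecule can be written with several equivalent breakpoint
pairs (the junction can slide along the repeat). :func:`adjust_breakpoint`
enumerates the equivalent placements and reports a canonical one; see
``CANONICAL_PLACEMENT``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

__all__ = [
    "GeneInterval",
    "MitoReference",
    "DeletionBreakpoint",
    "DeletionCatalog",
    "CatalogError",
    "ReferenceFormatError",
    "CANONICAL_PLACEMENT",
    "DEFAULT_BENCHMARK_WINDOWS",
    "DEFAULT_FLANK",
    "load_reference",
    "default_reference",
    "deleted_length",
    "build_deleted_genome",
    "build_junction_query",
    "find_flank_split",
    "adjust_breakpoint",
    "load_catalog",
    "default_catalog",
]

#: IUPAC nucleotide one-letter codes accepted in a reference sequence.
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")

#: Canonical placement for repeat-ambiguous junctions. "three_prime" slides
#: the junction as far 3' as the flanking repeat allows, i.e. the deletion is
#: named with the repeat copy retained on the 5' side. This reproduces the
#: adjusted anchors 6341-14005 and 8482-13460 for the 6335-13999 and
#: 8471-13449 deletions.
CANONICAL_PLACEMENT = "three_prime"

#: Two 250-bp benchmark windows used for the coverage denominator, placed
#: inside RNR1 (12S rRNA) and CYB. The exact window coordinates are a
#: configurable pipeline choice, not part of the deletion catalog.
DEFAULT_BENCHMARK_WINDOWS = ((701, 950), (15101, 15350))

#: Default number of retained bases on each side of a junction query.
DEFAULT_FLANK = 10

#: Standard gene intervals on the human mitochondrial genome (rCRS
#: numbering) for the genes referenced by the default catalog.
RCRS_GENES = (
    ("RNR1", 648, 1601),
    ("COX1", 5904, 7445),
    ("COX2", 7586, 8269),
    ("ATP8", 8366, 8572),
    ("ND5", 12337, 14148),
    ("CYB", 14747, 15887),
)


class ReferenceFormatError(ValueError):
    """Raised for malformed reference FASTA input."""


class CatalogError(ValueError):
    """Raised for invalid deletion-catalog rows."""


@dataclass(frozen=True)
class GeneInterval:
    name: str
    start: int
    end: int


@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial genome with benchmark windows.

    Parameters
    ----------
    name:
        Record label.
    sequence:
        Upper-case nucleotide string, 1-based addressing via :meth:`fetch`.
    benchmark_windows:
        Two equal-width genomic intervals used as the coverage denominator.
    genes:
        Optional gene intervals for annotation.
    """

    name: str
    sequence: str
    benchmark_windows: tuple[tuple[int, int], tuple[int, int]] = DEFAULT_BENCHMARK_WINDOWS
    genes: tuple[GeneInterval, ...] = tuple(GeneInterval(*g) for g in RCRS_GENES)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceFormatError("empty reference sequence")
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise ReferenceFormatError(
                f"non-IUPAC characters in reference: {sorted(bad)!r}"
            )
        (a1, a2), (b1, b2) = self.benchmark_windows
        for lo, hi in ((a1, a2), (b1, b2)):
            if not (1 <= lo <= hi <= self.length):
                raise ValueError(f"benchmark window ({lo}, {hi}) outside [1, {self.length}]")
        if (a2 - a1) != (b2 - b1):
            raise ValueError("benchmark windows must have identical width")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive, no wrapping)."""
        if not (1 <= start <= end <= self.length):
            raise IndexError(f"range {start}..{end} outside [1, {self.length}]")
        return self.sequence[start - 1 : end]

    def base(self, pos: int) -> str:
        """Return the base at circular position ``pos`` (wraps the origin)."""
        return self.sequence[(pos - 1) % self.length]


@dataclass(frozen=True)
class DeletionBreakpoint:
    """One deletion junction of the catalog.

    ``primary_query`` is the junction-spanning string a read must contain to
    be counted; ``aux_queries`` must additionally co-occur in the read (used
    when the primary query alone also matches wild-type sequence).
    """

    id: str
    b5: int
    b3: int
    flank5: int = DEFAULT_FLANK
    flank3: int = DEFAULT_FLANK
    primary_query: Optional[str] = None
    aux_queries: tuple[str, ...] = ()
    adj5: Optional[int] = None
    adj3: Optional[int] = None
    repeat_len: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.b5 < self.b3):
            raise CatalogError(f"{self.id}: require 1 <= b5 < b3, got ({self.b5}, {self.b3})")
        if self.b3 - self.b5 - 1 < 1:
            raise CatalogError(f"{self.id}: deleted length must be >= 1")
        if self.primary_query is not None and len(self.primary_query) != self.flank5 + self.flank3:
            raise CatalogError(
                f"{self.id}: primary_query length {len(self.primary_query)} != "
                f"flank5 + flank3 = {self.flank5 + self.flank3}"
            )
        if (self.adj5 is None) != (self.adj3 is None):
            raise CatalogError(f"{self.id}: adj5 and adj3 must be given together")
        if self.adj5 is not None and self.adj3 - self.adj5 != self.b3 - self.b5:
            raise CatalogError(f"{self.id}: adjusted pair must preserve the junction span")

    @property
    def deleted_length(self) -> int:
        return self.b3 - self.b5 - 1


@dataclass
class DeletionCatalog:
    """Ordered collection of deletion breakpoints.

    ``top_n`` controls how many entries are summed into the cumulative
    deletion metric (the full historical catalog has 30 entries; the shipped
    default carries the three printed breakpoints).
    """

    entries: list[DeletionBreakpoint] = field(default_factory=list)
    top_n: int = 30

    def __post_init__(self) -> None:
        ids = [bp.id for bp in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate catalog ids: {dupes}")
        self.entries.sort(key=lambda bp: (bp.b5, bp.b3))
        self.top_n = min(self.top_n, len(self.entries)) if self.entries else 0

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key):
        if isinstance(key, str):
            for bp in self.entries:
                if bp.id == key:
                    return bp
            raise KeyError(key)
        return self.entries[key]

    @property
    def ids(self) -> list[str]:
        return [bp.id for bp in self.entries]


def load_reference(path, benchmark_windows=DEFAULT_BENCHMARK_WINDOWS) -> MitoReference:
    """Load a single-record FASTA as a circular mitochondrial reference.

    Raises
    ------
    ReferenceFormatError
        If the file holds zero or more than one record, or the sequence
        contains non-IUPAC characters.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceFormatError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return MitoReference(
        name=rec.id,
        sequence=str(rec.seq).upper(),
        benchmark_windows=benchmark_windows,
    )


def default_reference() -> MitoReference:
    """Return the vendored synthetic rCRS-like reference.

    The shipped record is a 16,569-bp stand-in for the human rCRS built from
    a closely related public mitochondrial genome with coordinates
    normalized so that the catalog junction neighborhoods match the rCRS
    exactly (see the package data file header and docs/methods.md). It is
    not NC_012920.1 itself.
    """
    with resources.as_file(
        resources.files("mitodel").joinpath("data/mito_reference_synthetic.fa")
    ) as p:
        return load_reference(p)


def deleted_length(bp: DeletionBreakpoint) -> int:
    """Number of bases removed by the deletion: ``b3 - b5 - 1``."""
    return bp.deleted_length


def build_deleted_genome(ref: MitoReference, bp: DeletionBreakpoint) -> str:
    """Sequence of the deletion-bearing molecule (linearized at origin).

    Concatenates the retained arms ``ref[1..b5]`` and ``ref[b3..L]``; the
    result has length ``ref.length - deleted_length(bp)``.
    """
    return ref.fetch(1, bp.b5) + ref.fetch(bp.b3, ref.length)


def build_junction_query(
    ref: MitoReference, bp: DeletionBreakpoint, flank5: int, flank3: int
) -> str:
    """Junction-spanning string: ``flank5`` retained bases ending at ``b5``
    followed by ``flank3`` retained bases starting at ``b3``."""
    if flank5 < 0 or flank3 < 0 or flank5 + flank3 == 0:
        raise ValueError("flanks must be non-negative and not both zero")
    if flank5 > bp.b5:
        raise IndexError(f"flank5 {flank5} reaches past the reference start (b5={bp.b5})")
    if bp.b3 + flank3 - 1 > ref.length:
        raise IndexError(f"flank3 {flank3} reaches past the reference end (b3={bp.b3})")
    left = ref.fetch(bp.b5 - flank5 + 1, bp.b5) if flank5 else ""
    right = ref.fetch(bp.b3, bp.b3 + flank3 - 1) if flank3 else ""
    return left + right


def find_flank_split(
    ref: MitoReference, bp: DeletionBreakpoint, query: str
) -> list[tuple[int, int]]:
    """All flank splits (flank5, flank3) under which ``query`` is the
    junction string of ``bp``. Exhaustive over 0..len(query)."""
    hits = []
    for f5 in range(len(query) + 1):
        f3 = len(query) - f5
        if f5 > bp.b5 or bp.b3 + f3 - 1 > ref.length or f5 + f3 == 0:
            continue
        if build_junction_query(ref, bp, f5, f3) == query:
            hits.append((f5, f3))
    return hits


def _equivalent_range(ref: MitoReference, bp: DeletionBreakpoint) -> tuple[int, int]:
    """Range [lo, hi] of b5 values whose deletion of the same span yields an
    identical deleted genome (the junction slid along the flanking repeat)."""
    span = bp.b3 - bp.b5
    seq = ref.sequence
    lo = bp.b5
    # (p, q) -> (p-1, q-1) leaves the molecule unchanged iff ref[p] == ref[q-1]
    while lo > 1 and lo + span - 1 <= ref.length and seq[lo - 1] == seq[lo + span - 2]:
        lo -= 1
    hi = bp.b5
    while hi + span < ref.length and seq[hi] == seq[hi + span - 1]:
        hi += 1
    return lo, hi


def adjust_breakpoint(
    ref: MitoReference, bp: DeletionBreakpoint, convention: str = CANONICAL_PLACEMENT
) -> tuple[int, int, int]:
    """Canonical (adj5, adj3, repeat_len) for a repeat-ambiguous junction.

    All breakpoint placements producing a deleted genome identical to that
    of ``bp`` are enumerated; ``repeat_len`` is the number of equivalent
    placements minus one (0 when no repeat flanks the junction, in which
    case the adjusted pair equals the raw pair). The canonical placement is
    selected by ``convention``:

    - ``"three_prime"``: the 3'-most placement (repeat retained 5' of the
      junction);
    - ``"five_prime"``: the 5'-most placement.

    The function is idempotent: adjusting an already-canonical placement
    returns it unchanged.
    """
    lo, hi = _equivalent_range(ref, bp)
    if convention == "three_prime":
        a5 = hi
    elif convention == "five_prime":
        a5 = lo
    else:
        raise ValueError(f"unknown placement convention {convention!r}")
    return a5, bp.b3 + (a5 - bp.b5), hi - lo


_CATALOG_COLUMNS = {"id", "b5", "b3"}


def load_catalog(path, ref: MitoReference, top_n: int = 30) -> DeletionCatalog:
    """Load a tab-delimited deletion catalog and validate it.

    Required columns: ``id``, ``b5``, ``b3``. Optional: ``flank5``,
    ``flank3``, ``query``, ``aux_queries`` (semicolon-separated), ``adj5``,
    ``adj3``. Missing queries are synthesized with
    :func:`build_junction_query`; missing adjusted coordinates with
    :func:`adjust_breakpoint`.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        warnings.warn(f"empty deletion catalog: {path}")
        return DeletionCatalog([], top_n=top_n)
    header = lines[0].split("\t")
    missing = _CATALOG_COLUMNS - set(header)
    if missing:
        raise CatalogError(f"{path}: missing required columns {sorted(missing)}")
    entries = []
    for rowno, ln in enumerate(lines[1:], start=2):
        fields = dict(zip(header, ln.split("\t")))
        try:
            b5, b3 = int(fields["b5"]), int(fields["b3"])
            if not (1 <= b5 < b3 <= ref.length):
                raise CatalogError(
                    f"coordinates ({b5}, {b3}) out of range [1, {ref.length}]"
                )
            f5 = int(fields.get("flank5") or DEFAULT_FLANK)
            f3 = int(fields.get("flank3") or DEFAULT_FLANK)
            aux = tuple(q for q in (fields.get("aux_queries") or "").split(";") if q)
            bp = DeletionBreakpoint(
                id=fields["id"], b5=b5, b3=b3, flank5=f5, flank3=f3,
                primary_query=fields.get("query") or None, aux_queries=aux,
                adj5=int(fields["adj5"]) if fields.get("adj5") else None,
                adj3=int(fields["adj3"]) if fields.get("adj3") else None,
            )
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path} row {rowno}: {exc}") from exc
        entries.append(_complete_breakpoint(ref, bp))
    return DeletionCatalog(entries, top_n=top_n)


def _complete_breakpoint(ref: MitoReference, bp: DeletionBreakpoint) -> DeletionBreakpoint:
    """Fill in query and adjusted coordinates where absent."""
    if bp.primary_query is None:
        bp = replace(bp, primary_query=build_junction_query(ref, bp, bp.flank5, bp.flank3))
    if bp.adj5 is None:
        a5, a3, rl = adjust_breakpoint(ref, bp)
        bp = replace(bp, adj5=a5, adj3=a3, repeat_len=rl)
    elif bp.repeat_len is None:
        _, _, rl = adjust_breakpoint(ref, bp)
        bp = replace(bp, repeat_len=rl)
    return bp


def default_catalog(ref: Optional[MitoReference] = None) -> DeletionCatalog:
    """The shipped three-breakpoint catalog, completed against ``ref``.

    Entries: 6335-13999 (flanks 10+10), 7816-14807 (flanks 8+10 with the two
    auxiliary specificity strings), and 8471-13449 (flanks 15+15).
    """
    if ref is None:
        ref = default_reference()
    with resources.as_file(
        resources.files("mitodel").joinpath("data/default_catalog.tsv")
    ) as p:
        return load_catalog(p, ref)
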