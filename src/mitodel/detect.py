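"""Junction-read detection, benchmark coverage, and per-sample metrics.

The detector mirrors the operational definition used for catalog junctions:
a read supports a deletion iff its sequence contains the deletion's
junction-spanning query string and, when the catalog entry carries
auxiliary strings, all of those as well (all on the same strand). Counts
are normalized by the MT benchmark coverage — the mean sequencing depth
over two fixed 250-bp windows — giving the per-sample deletion read %:

    read_pct = 100 * deletion_reads / mt_benchmark_coverage

``discover_junctions`` is a catalog-free split-read discoverer for
error-free or low-error reads: it anchors the longest exact prefix and
suffix of each read on the reference and emits the implied junction when
the two anchors cover the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

from .refcat import DeletionBreakpoint, DeletionCatalog, MitoReference, adjust_breakpoint

__all__ = [
    "ReadRecord",
    "ScanResult",
    "SampleMetrics",
    "Junction",
    "FastqParseError",
    "read_fastq",
    "reverse_complement",
    "read_matches",
    "scan_reads",
    "benchmark_coverage",
    "compute_metrics",
    "discover_junctions",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised when a FASTQ stream is unreadable, with the record index."""


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: id (header token before whitespace), sequence,
    and mate number (1, 2, or 0 for unpaired)."""

    read_id: str
    sequence: str
    mate: int = 0


def read_fastq(path, mate: int = 0) -> Iterator[ReadRecord]:
    """Stream records from a FASTQ or FASTQ.gz file.

    Truncated or corrupt input raises :class:`FastqParseError` naming the
    file and the index of the failing record.
    """
    idx = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                idx += 1
                yield ReadRecord(entry.name, entry.sequence.upper(), mate)
    except FastqParseError:
        raise
    except Exception as exc:  # truncated gzip, malformed record, ...
        raise FastqParseError(f"{path}: unreadable FASTQ at record {idx + 1}: {exc}") from exc


def _as_records(reads: Iterable) -> Iterator[ReadRecord]:
    for i, r in enumerate(reads):
        if isinstance(r, ReadRecord):
            yield r
        elif isinstance(r, str):
            yield ReadRecord(f"read{i}", r.upper())
        else:  # (id, seq) pair
            yield ReadRecord(r[0], r[1].upper())


def read_matches(sequence: str, bp: DeletionBreakpoint, orientation: str = "forward_only") -> bool:
    """Containment rule for one read against one catalog entry.

    The primary query and every auxiliary query must all occur in the read
    on the same strand. With ``orientation="both"`` the reverse complement
    of the read is tested as well.
    """
    queries = (bp.primary_query, *bp.aux_queries)
    if any(q is None for q in queries):
        raise ValueError(f"catalog entry {bp.id} has no primary_query")
    if all(q in sequence for q in queries):
        return True
    if orientation == "both":
        rc = reverse_complement(sequence)
        return all(q in rc for q in queries)
    if orientation != "forward_only":
        raise ValueError(f"unknown orientation {orientation!r}")
    return False


@dataclass
class ScanResult:
    counts: dict[str, int]
    matched_read_ids: dict[str, list[str]]
    total_reads: int


def scan_reads(
    reads: Iterable,
    catalog: DeletionCatalog,
    orientation: str = "forward_only",
) -> ScanResult:
    """Count reads supporting each catalog deletion.

    Each read is counted at most once per deletion (but may support several
    deletions). The counting unit is reads, not read pairs: both mates of a
    pair matching a junction contribute two counts, as a grep over split
    FASTQ files would.
    """
    counts = {bp.id: 0 for bp in catalog}
    matched: dict[str, list[str]] = {bp.id: [] for bp in catalog}
    total = 0
    for rec in _as_records(reads):
        total += 1
        for bp in catalog:
            if read_matches(rec.sequence, bp, orientation):
                counts[bp.id] += 1
                matched[bp.id].append(rec.read_id)
    return ScanResult(counts=counts, matched_read_ids=matched, total_reads=total)


def _best_placement(
    doubled: str, length: int, seq: str, max_mismatches: int
) -> Optional[int]:
    """1-based start of the best placement of ``seq`` on the circular
    reference (represented by its doubled string), or None.

    Exact search uses substring find; with mismatches allowed, the leftmost
    placement achieving the minimum mismatch count (<= max_mismatches)
    wins. Ties break to the smallest coordinate.
    """
    if len(seq) > length:
        return None
    if max_mismatches == 0:
        i = doubled.find(seq, 0, length + len(seq) - 1)
        return i + 1 if i >= 0 else None
    best, best_pos = max_mismatches + 1, None
    for start in range(length):
        window = doubled[start : start + len(seq)]
        mm = 0
        for a, b in zip(window, seq):
            if a != b:
                mm += 1
                if mm >= best:
                    break
        if mm < best:
            best, best_pos = mm, start + 1
            if best == 0:
                break
    return best_pos


def _window_overlap(start: int, read_len: int, win: tuple[int, int], length: int) -> int:
    """Bases of a read placed at circular position ``start`` overlapping a
    window, counting the window's image in both copies of the doubled
    reference (reads may wrap the origin)."""
    lo, hi = start, start + read_len - 1
    total = 0
    for shift in (0, length):
        w1, w2 = win[0] + shift, win[1] + shift
        total += max(0, min(hi, w2) - max(lo, w1) + 1)
    return total


def benchmark_coverage(
    reads: Iterable,
    ref: MitoReference,
    max_mismatches: int = 0,
    orientation: str = "both",
) -> float:
    """Mean depth over the benchmark windows.

    Each read is located on the circular reference at its best exact (or
    <= max_mismatches) placement; reads that do not place contribute
    nothing. Coverage = total read bases overlapping the two windows
    divided by the total window width. Forward placement is preferred over
    reverse-complement when both exist; ambiguous placements take the
    smallest coordinate.
    """
    doubled = ref.sequence * 2
    width = sum(w[1] - w[0] + 1 for w in ref.benchmark_windows)
    n = overlap = 0
    for rec in _as_records(reads):
        n += 1
        pos = _best_placement(doubled, ref.length, rec.sequence, max_mismatches)
        if pos is None and orientation == "both":
            pos = _best_placement(
                doubled, ref.length, reverse_complement(rec.sequence), max_mismatches
            )
        if pos is None:
            continue
        for win in ref.benchmark_windows:
            overlap += _window_overlap(pos, len(rec.sequence), win, ref.length)
    if n == 0:
        import warnings

        warnings.warn("benchmark_coverage: empty read stream, coverage is 0")
    return overlap / width


@dataclass
class SampleMetrics:
    """Per-sample deletion metrics table row."""

    sample_id: str
    total_reads: int
    mt_benchmark_coverage: float
    read_counts: dict[str, int]
    read_pct: dict[str, Optional[float]]
    cumulative_top_pct: Optional[float]
    matched_read_ids: dict[str, list[str]] = field(default_factory=dict)
    inconsistent: bool = False

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "total_reads": self.total_reads,
            "mt_benchmark_coverage": self.mt_benchmark_coverage,
        }
        for del_id, pct in self.read_pct.items():
            row[f"pct_{del_id}"] = pct
        row["cumulative_top_pct"] = self.cumulative_top_pct
        return row


def compute_metrics(
    counts: dict[str, int],
    coverage: float,
    total_reads: int,
    catalog: DeletionCatalog,
    sample_id: str = "sample",
    matched_read_ids: Optional[dict[str, list[str]]] = None,
) -> SampleMetrics:
    """Normalize junction counts by benchmark coverage.

    ``read_pct = 100 * count / coverage`` per deletion; the cumulative
    metric sums the catalog's ``top_n`` entries. With zero coverage the
    percentages are reported missing (None), and nonzero counts at zero
    coverage flag the sample inconsistent.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    inconsistent = coverage == 0 and any(c > 0 for c in counts.values())
    pct: dict[str, Optional[float]] = {}
    for bp in catalog:
        c = counts.get(bp.id, 0)
        pct[bp.id] = None if coverage == 0 else 100.0 * c / coverage
    top_ids = catalog.ids[: catalog.top_n]
    cumulative = (
        None if coverage == 0 else sum(pct[i] for i in top_ids)  # type: ignore[misc]
    )
    return SampleMetrics(
        sample_id=sample_id,
        total_reads=total_reads,
        mt_benchmark_coverage=coverage,
        read_counts=dict(counts),
        read_pct=pct,
        cumulative_top_pct=cumulative,
        matched_read_ids=matched_read_ids or {},
        inconsistent=inconsistent,
    )


@dataclass(frozen=True)
class Junction:
    b5: int
    b3: int
    support: int


def _longest_prefix_placement(doubled: str, length: int, seq: str) -> tuple[int, int]:
    """(placement start, matched length) of the longest prefix of ``seq``
    occurring in the circular reference; leftmost placement on ties."""
    lo, hi = 0, len(seq)
    # binary search on matchable prefix length; occurrence is monotone
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if doubled.find(seq[:mid], 0, length + mid - 1) >= 0:
            lo = mid
        else:
            hi = mid - 1
    if lo == 0:
        return 0, 0
    return doubled.find(seq[:lo], 0, length + lo - 1) + 1, lo


def discover_junctions(
    reads: Iterable,
    ref: MitoReference,
    min_anchor: int = 20,
    max_candidates: Optional[int] = None,
) -> list[Junction]:
    """Catalog-free split-read junction discovery (exact anchors).

    For each read the longest exact prefix and suffix placements on the
    circular reference are found. When the two anchors are each at least
    ``min_anchor`` bases, together cover the read, and imply a deletion of
    at least one base, the junction is recorded. Anchors may overlap (the
    direct-repeat ambiguity); the junction is taken at the maximal-prefix
    split and then canonicalized with :func:`adjust_breakpoint`, so all
    equivalent placements aggregate. Results are sorted by decreasing
    support, then coordinates.
    """
    doubled = ref.sequence * 2
    L = ref.length
    counts: dict[tuple[int, int], int] = {}
    for rec in _as_records(reads):
        seq = rec.sequence
        n = len(seq)
        p_start, p_len = _longest_prefix_placement(doubled, L, seq)
        if p_len == n or p_len < min_anchor:
            continue  # fully wild-type, or 5' anchor too short
        rev = seq[::-1]
        s_start_rev, s_len = _longest_prefix_placement(doubled[::-1], L, rev)
        if s_len < min_anchor or p_len + s_len < n:
            continue  # 3' anchor too short, or anchors leave a gap
        # suffix occupies doubled[(2L - s_start_rev - s_len + 1) .. ], 1-based
        s_start = 2 * L - s_start_rev - s_len + 2
        overlap = p_len + s_len - n
        b5 = p_start + p_len - 1  # prefix end (maximal-prefix split)
        b3 = s_start + overlap  # suffix start advanced past the overlap
        # map into [1, L] on the circle
        b5 = (b5 - 1) % L + 1
        b3 = (b3 - 1) % L + 1
        if b3 <= b5 + 1:
            continue
        raw = DeletionBreakpoint(id=f"{b5}-{b3}", b5=b5, b3=b3)
        a5, a3, _ = adjust_breakpoint(ref, raw)
        counts[(a5, a3)] = counts.get((a5, a3), 0) + 1
    out = sorted(
        (Junction(b5, b3, c) for (b5, b3), c in counts.items()),
        key=lambda j: (-j.support, j.b5, j.b3),
    )
    if max_candidates is not None:
        out = out[:max_candidates]
    return out
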