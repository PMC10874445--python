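"""Spot-barcode deletion mapping and cortical layer imputation.

In 10x Visium-style libraries Read 1 carries the spot barcode (first 16 nt
by default) and UMI; Read 2 carries the cDNA. Junction-containing Read 2
records are cross-referenced by read id with Read 1 to recover their spot
barcode, and a spot is a "deletion spot" for a catalog entry when at least
one of its reads matches that entry's query rule. Flags are boolean per
spot, which makes the result invariant to UMI duplication.

Clusters from expression-based clustering are assigned to cortical layers
by overlap with ground-truth (histology-derived) annotations: a cluster is
assigned to a layer only when strictly more than ``min_overlap`` (default
40%) of its spots fall in that layer, and clusters with overall frequency
below ``min_frequency`` (default 5%) stay unassigned. Per-layer deletion-
spot proportions are compared with pooled two-proportion Z-tests.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .detect import _as_records, read_fastq, read_matches
from .refcat import DeletionCatalog

__all__ = [
    "DEFAULT_BARCODE_LEN",
    "DEFAULT_UMI_LEN",
    "normalize_read_id",
    "extract_barcodes",
    "SpotBarcodeIndex",
    "SpotDeletionCalls",
    "call_deletion_spots",
    "LayerImputation",
    "impute_layers",
    "layer_counts",
    "pool_layer_counts",
    "two_proportion_z",
    "layer_proportion_test",
    "significance_letters",
]

DEFAULT_BARCODE_LEN = 16
DEFAULT_UMI_LEN = 12

_MATE_SUFFIX = re.compile(r"/[12]$")


def normalize_read_id(read_id: str) -> str:
    """Strip whitespace-delimited comments and /1, /2 mate suffixes so that
    Read1 and Read2 headers of the same fragment compare equal."""
    head = read_id.split()[0]
    return _MATE_SUFFIX.sub("", head)


def extract_barcodes(
    read1: Iterable, barcode_len: int = DEFAULT_BARCODE_LEN, umi_len: int = DEFAULT_UMI_LEN
) -> tuple[dict[str, str], int]:
    """Map normalized read id -> spot barcode from a Read 1 stream.

    ``read1`` may be a path to a FASTQ(.gz) file or an iterable of records.
    Records shorter than ``barcode_len`` are skipped; the second return
    value counts them. ``umi_len`` documents the expected geometry but the
    UMI itself is not used (spot flags are boolean).
    """
    if isinstance(read1, (str,)) or hasattr(read1, "__fspath__"):
        read1 = read_fastq(read1, mate=1)
    mapping: dict[str, str] = {}
    skipped = 0
    for rec in _as_records(read1):
        if len(rec.sequence) < barcode_len:
            skipped += 1
            continue
        mapping[normalize_read_id(rec.read_id)] = rec.sequence[:barcode_len]
    if skipped:
        warnings.warn(f"extract_barcodes: skipped {skipped} record(s) shorter than barcode")
    if not mapping:
        warnings.warn("extract_barcodes: empty Read 1 stream")
    return mapping, skipped


@dataclass
class SpotBarcodeIndex:
    """Read-id -> barcode mapping plus spot annotations."""

    read_to_barcode: dict[str, str]
    whitelist: frozenset[str]
    barcode_to_cluster: dict[str, str] = field(default_factory=dict)
    cluster_to_layer: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lens = {len(b) for b in self.whitelist}
        if len(lens) > 1:
            raise ValueError(f"whitelist barcode lengths differ: {sorted(lens)}")


@dataclass
class SpotDeletionCalls:
    """Per-spot deletion flags: barcode -> set of deletion ids."""

    flags: dict[str, set[str]]
    deletion_ids: list[str]
    n_whitelisted: int
    discarded_reads: int

    def spots_with(self, deletion_id: str) -> set[str]:
        return {bc for bc, dels in self.flags.items() if deletion_id in dels}


def call_deletion_spots(
    read2: Iterable,
    catalog: DeletionCatalog,
    index: SpotBarcodeIndex,
    orientation: str = "forward_only",
) -> SpotDeletionCalls:
    """Flag spots whose Read 2 sequences contain catalog junctions.

    A spot is flagged for a deletion iff at least one of its reads matches
    that deletion's containment rule (primary query plus any auxiliary
    queries, as in bulk scanning). Junction reads whose barcode is missing
    from the whitelist are discarded and counted.
    """
    if isinstance(read2, (str,)) or hasattr(read2, "__fspath__"):
        read2 = read_fastq(read2, mate=2)
    flags: dict[str, set[str]] = {}
    discarded = 0
    for rec in _as_records(read2):
        hits = [bp.id for bp in catalog if read_matches(rec.sequence, bp, orientation)]
        if not hits:
            continue
        barcode = index.read_to_barcode.get(normalize_read_id(rec.read_id))
        if barcode is None or barcode not in index.whitelist:
            discarded += 1
            continue
        flags.setdefault(barcode, set()).update(hits)
    return SpotDeletionCalls(
        flags=flags,
        deletion_ids=catalog.ids,
        n_whitelisted=len(index.whitelist),
        discarded_reads=discarded,
    )


@dataclass
class LayerImputation:
    """Cluster -> layer assignment with its supporting overlap matrix."""

    overlap: pd.DataFrame  # clusters x layers, proportions of cluster spots
    frequencies: pd.Series  # overall cluster frequencies
    assignment: dict[str, str]  # assigned clusters only
    unassigned: list[str]


def impute_layers(
    cluster_assignments: Mapping[str, str],
    ground_truth: Mapping[str, str],
    min_overlap: float = 0.40,
    min_frequency: float = 0.05,
) -> LayerImputation:
    """Assign clusters to layers by ground-truth overlap.

    Both mappings are barcode-keyed; the overlap matrix is computed on the
    intersection of their barcode universes. A cluster is assigned to the
    layer holding its maximum overlap only when that overlap is strictly
    greater than ``min_overlap``; clusters with overall frequency below
    ``min_frequency`` are never assigned. Multiple clusters may map to the
    same layer.
    """
    common = set(cluster_assignments) & set(ground_truth)
    if not common:
        raise ValueError("cluster and ground-truth annotations share no barcodes")
    df = pd.DataFrame(
        {
            "cluster": [str(cluster_assignments[b]) for b in common],
            "layer": [str(ground_truth[b]) for b in common],
        }
    )
    counts = df.groupby(["cluster", "layer"]).size().unstack(fill_value=0)
    counts = counts.sort_index().sort_index(axis=1)
    overlap = counts.div(counts.sum(axis=1), axis=0)
    freqs = counts.sum(axis=1) / len(df)
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for cluster in overlap.index:
        best_layer = overlap.loc[cluster].idxmax()
        best = overlap.loc[cluster, best_layer]
        if freqs[cluster] < min_frequency or not best > min_overlap:
            unassigned.append(cluster)
        else:
            assignment[cluster] = best_layer
    return LayerImputation(
        overlap=overlap, frequencies=freqs, assignment=assignment, unassigned=unassigned
    )


def layer_counts(
    calls: SpotDeletionCalls,
    index: SpotBarcodeIndex,
    deletion_id: str,
    layers: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-layer spot totals and deletion-spot counts for one deletion.

    ``layers`` maps cluster label -> layer label (e.g. from
    :func:`impute_layers`); spots in unassigned clusters are excluded.
    Returns a table with columns layer, n_spots, n_deletion_spots,
    proportion.
    """
    layers = dict(layers) if layers is not None else dict(index.cluster_to_layer)
    flagged = calls.spots_with(deletion_id)
    rows: dict[str, list[int]] = {}
    for bc in index.whitelist:
        cluster = index.barcode_to_cluster.get(bc)
        if cluster is None:
            continue
        layer = layers.get(str(cluster))
        if layer is None:
            continue
        n, d = rows.setdefault(layer, [0, 0])
        rows[layer][0] = n + 1
        rows[layer][1] = d + (1 if bc in flagged else 0)
    out = pd.DataFrame(
        [
            {"layer": lay, "n_spots": n, "n_deletion_spots": d,
             "proportion": d / n if n else np.nan}
            for lay, (n, d) in sorted(rows.items())
        ]
    )
    return out


def pool_layer_counts(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-section layer tables by summing numerators and denominators."""
    cat = pd.concat(list(tables), ignore_index=True)
    pooled = cat.groupby("layer", as_index=False)[["n_spots", "n_deletion_spots"]].sum()
    pooled["proportion"] = pooled["n_deletion_spots"] / pooled["n_spots"]
    return pooled


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion Z statistic and two-sided p-value."""
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def layer_proportion_test(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-proportion Z-tests between layers.

    ``counts`` must have columns layer, n_spots, n_deletion_spots (e.g.
    from :func:`layer_counts` or :func:`pool_layer_counts`). Layers with
    zero spots are excluded with a warning. Identical proportions give
    Z = 0, p = 1. The result carries one row per layer pair plus a
    ``significant`` flag at ``alpha``.
    """
    usable = counts[counts["n_spots"] > 0]
    if len(usable) < len(counts):
        warnings.warn("layer_proportion_test: excluded layer(s) with zero spots")
    rows = []
    recs = usable.set_index("layer")
    for a, b in itertools.combinations(sorted(recs.index), 2):
        x1, n1 = int(recs.loc[a, "n_deletion_spots"]), int(recs.loc[a, "n_spots"])
        x2, n2 = int(recs.loc[b, "n_deletion_spots"]), int(recs.loc[b, "n_spots"])
        if x1 * n2 == x2 * n1:  # equal proportions (incl. both zero)
            z, p = 0.0, 1.0
        else:
            z, p = two_proportion_z(x1, n1, x2, n2)
        rows.append(
            {"layer_a": a, "layer_b": b, "z": z, "p": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def significance_letters(pairwise: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from pairwise test results.

    Two layers share a letter iff they are not significantly different at
    the test's alpha (insert-and-absorb construction: start from one group
    holding every layer, split each group that contains a significantly
    different pair, then drop groups contained in another).
    """
    layers = sorted(set(pairwise["layer_a"]) | set(pairwise["layer_b"]))
    differ = {
        frozenset((r.layer_a, r.layer_b)) for r in pairwise.itertuples() if r.significant
    }
    groups: list[set[str]] = [set(layers)]
    for pair in differ:
        a, b = sorted(pair)
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            groups.extend((g - {a}, g - {b}))
        groups = [g for g in groups if not any(g < h for h in groups if h is not g)]
    groups.sort(key=lambda g: sorted(g))
    letters: dict[str, str] = {lay: "" for lay in layers}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lay in sorted(g):
            letters[lay] += letter
    return letters
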