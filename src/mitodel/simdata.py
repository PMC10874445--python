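"""Synthetic read and cohort generators with recorded ground truth.

Every generator is a pure function of its parameters and seed, so repeated
runs are byte-identical. The generators emulate the statistical structure
the analysis assumes:

- :func:`simulate_sample` draws reads from a mixture of wild-type and
  deletion-bearing circular mitochondrial molecules plus random decoy
  (non-mitochondrial) sequence, with uniform substitution errors;
- :func:`simulate_paired_platforms` draws matched DNA/RNA cohorts sharing
  a latent per-sample deletion burden with a platform fold-scaling;
- :func:`simulate_cohort_ages` draws a cohort with an age-dependent
  deletion burden plus coverage and sex effects;
- :func:`simulate_spatial` lays out spots in cortical layers with
  layer-specific deletion-spot probabilities and emits Read1/Read2 pairs,
  a barcode whitelist, and cluster / ground-truth tables.

Expectation helpers (:func:`expected_read_pct`,
:func:`expected_benchmark_coverage`) compute the analytic values the
recovery tests compare against, by exact enumeration of read placements —
no re-reading of the generated FASTQ is needed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import ReadRecord, _window_overlap
from .refcat import DeletionCatalog, MitoReference, build_deleted_genome

__all__ = [
    "SampleTruth",
    "PairedPlatformTruth",
    "AgeCohortTruth",
    "SpatialTruth",
    "SpatialData",
    "simulate_sample",
    "simulate_paired_platforms",
    "simulate_cohort_ages",
    "simulate_spatial",
    "expected_read_pct",
    "expected_benchmark_coverage",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated bulk library.

    ``mt_fraction`` is the share of reads drawn from mitochondrial
    molecules (the rest are uniform-random decoys, standing in for the
    nuclear background); ``junction_fractions`` give, per catalog deletion,
    the share of mitochondrial reads drawn from that deleted genome.
    """

    seed: int
    n_reads: int = 100_000
    read_len: int = 100
    mt_fraction: float = 0.2
    junction_fractions: dict = field(default_factory=dict)
    error_rate: float = 0.0
    sample_id: str = "sim"

    def __post_init__(self):
        if not (0.0 <= self.mt_fraction <= 1.0):
            raise ValueError("mt_fraction must lie in [0, 1]")
        if any(f < 0 for f in self.junction_fractions.values()):
            raise ValueError("junction fractions must be >= 0")
        if sum(self.junction_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("junction fractions must sum to <= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")


def _draw_from_circle(rng, genome: str, read_len: int, n: int) -> list[str]:
    if read_len > len(genome):
        raise ValueError(f"read_len {read_len} exceeds genome length {len(genome)}")
    doubled = genome + genome[: read_len - 1]
    starts = rng.integers(0, len(genome), size=n)
    return [doubled[s : s + read_len] for s in starts]


def _apply_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    if not hit.any():
        return seq
    for i in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_sample(
    ref: MitoReference, catalog: DeletionCatalog, truth: SampleTruth
) -> list[ReadRecord]:
    """Simulate one library of single-end reads.

    Reads are drawn uniformly from the circular wild-type genome, from each
    deleted genome according to ``junction_fractions``, or as uniform
    random decoy sequence. The seed and the source molecule are recorded in
    every read header.
    """
    rng = np.random.default_rng(truth.seed)
    sources = ["wt"] + [bp.id for bp in catalog] + ["decoy"]
    jf = [truth.junction_fractions.get(bp.id, 0.0) for bp in catalog]
    probs = np.array(
        [truth.mt_fraction * (1.0 - sum(jf))]
        + [truth.mt_fraction * f for f in jf]
        + [1.0 - truth.mt_fraction]
    )
    genomes = {"wt": ref.sequence}
    for bp in catalog:
        genomes[bp.id] = build_deleted_genome(ref, bp)
        if truth.read_len > len(genomes[bp.id]):
            raise ValueError(
                f"read_len {truth.read_len} exceeds deleted genome {bp.id}"
            )
    labels = rng.choice(len(sources), size=truth.n_reads, p=probs)
    reads: list[ReadRecord] = []
    for i, lab in enumerate(labels):
        src = sources[lab]
        if src == "decoy":
            seq = "".join(
                _BASES[rng.integers(0, 4, size=truth.read_len)].astype("U1")
            )
        else:
            seq = _draw_from_circle(rng, genomes[src], truth.read_len, 1)[0]
            seq = _apply_errors(rng, seq, truth.error_rate)
        rid = f"{truth.sample_id}:seed{truth.seed}:{src}:{i}"
        reads.append(ReadRecord(rid, seq))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write records as FASTQ (gzip-compressed if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in reads:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")


def _valid_starts(genome: str, read_len: int, queries: Sequence[str]) -> list[int]:
    """Start positions (0-based, circular) whose read contains all queries."""
    doubled = genome + genome[: read_len - 1]
    out = []
    for s in range(len(genome)):
        window = doubled[s : s + read_len]
        if all(q in window for q in queries):
            out.append(s)
    return out


def expected_read_pct(
    ref: MitoReference, catalog: DeletionCatalog, truth: SampleTruth, deletion_id: str
) -> tuple[float, float]:
    """Analytic expectation (value, binomial SE) of a deletion's read %.

    The per-read probability of supporting the deletion is the fraction of
    start positions on its circular deleted genome from which a read of the
    configured length contains the primary and all auxiliary queries
    (enumerated exactly), times the probability of drawing a read from that
    molecule. The percentage uses the expected benchmark coverage as the
    denominator; the SE propagates the binomial count variance only. Exact
    for error-free reads.
    """
    bp = catalog[deletion_id]
    genome = build_deleted_genome(ref, bp)
    starts = _valid_starts(genome, truth.read_len, (bp.primary_query, *bp.aux_queries))
    p_span = len(starts) / len(genome)
    p_read = truth.mt_fraction * truth.junction_fractions.get(deletion_id, 0.0) * p_span
    exp_count = truth.n_reads * p_read
    exp_cov = expected_benchmark_coverage(ref, catalog, truth)
    se_count = np.sqrt(truth.n_reads * p_read * (1 - p_read))
    return 100.0 * exp_count / exp_cov, 100.0 * se_count / exp_cov


def expected_benchmark_coverage(
    ref: MitoReference, catalog: DeletionCatalog, truth: SampleTruth
) -> float:
    """Expected mean depth over the benchmark windows.

    Enumerates, for each source molecule, every read start position and the
    window overlap of its exact placement on the wild-type reference. Reads
    from deleted molecules that span the junction are treated as unplaced
    (their sequence is junction-specific), matching the detector's exact
    placement rule for error-free reads.
    """
    width = sum(w[1] - w[0] + 1 for w in ref.benchmark_windows)
    L = ref.length
    jf = {bp.id: truth.junction_fractions.get(bp.id, 0.0) for bp in catalog}
    per_source = {}
    # wild type: every circular start places at itself
    total = 0
    for s in range(L):
        for win in ref.benchmark_windows:
            total += _window_overlap(s + 1, truth.read_len, win, L)
    per_source["wt"] = total / L
    for bp in catalog:
        if jf[bp.id] == 0:
            continue
        g_len = L - bp.deleted_length
        total = 0
        for s in range(g_len):
            # map deleted-genome start to reference coordinates; reads
            # crossing the junction or wrapping through it are unplaced
            if s + truth.read_len <= bp.b5:  # wholly in 5' arm
                pos = s + 1
            elif s >= bp.b5:  # wholly in 3' arm (may wrap the origin)
                pos = bp.b3 + (s - bp.b5)
            else:
                continue
            for win in ref.benchmark_windows:
                total += _window_overlap(pos, truth.read_len, win, L)
        per_source[bp.id] = total / g_len
    n_mt = truth.n_reads * truth.mt_fraction
    exp_bases = n_mt * (1 - sum(jf.values())) * per_source["wt"]
    for bp in catalog:
        if jf[bp.id] > 0:
            exp_bases += n_mt * jf[bp.id] * per_source[bp.id]
    return exp_bases / width


@dataclass(frozen=True)
class PairedPlatformTruth:
    """Matched DNA/RNA design: shared latent burden, platform fold-scaling.

    Defaults mirror the paired-brain-cohort design this package targets:
    30 matched samples and a 22-fold DNA excess for the common deletion.
    """

    seed: int
    n_samples: int = 30
    fold_factor: float = 22.0
    noise_sd: float = 0.5
    latent_log_mean: float = np.log(0.01)
    latent_log_sd: float = 1.0


def simulate_paired_platforms(
    truth: PairedPlatformTruth, metrics: Sequence[str] = ("pct_8471-13449",)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two matched cohort tables (DNA, RNA) sharing latent burdens.

    For each metric: DNA = fold_factor x latent x lognormal noise,
    RNA = latent x lognormal noise.
    """
    rng = np.random.default_rng(truth.seed)
    ids = [f"s{i:03d}" for i in range(truth.n_samples)]
    dna = pd.DataFrame({"sample_id": ids})
    rna = pd.DataFrame({"sample_id": ids})
    for m in metrics:
        latent = np.exp(
            rng.normal(truth.latent_log_mean, truth.latent_log_sd, truth.n_samples)
        )
        dna[m] = truth.fold_factor * latent * np.exp(
            rng.normal(0, truth.noise_sd, truth.n_samples)
        )
        rna[m] = latent * np.exp(rng.normal(0, truth.noise_sd, truth.n_samples))
    return dna, rna


@dataclass(frozen=True)
class AgeCohortTruth:
    """Cohort with an age-dependent deletion burden.

    The slope is in metric units per year; coverage and sex act as nuisance
    covariates as in the regression design the cohort is analyzed with.
    """

    seed: int
    n: int = 60
    age_range: tuple[int, int] = (20, 96)
    slope: float = 0.005
    intercept: float = 0.05
    noise_sd: float = 0.05
    coverage_log_mean: float = np.log(5e4)
    coverage_log_sd: float = 0.5
    coverage_beta: float = 1e-7
    sex_beta: float = 0.01
    metric: str = "pct_8471-13449"


def simulate_cohort_ages(truth: AgeCohortTruth) -> pd.DataFrame:
    """One cohort table: metric = intercept + slope*age + covariate effects
    + Gaussian noise. Other metric columns carry age-independent noise."""
    rng = np.random.default_rng(truth.seed)
    ages = rng.integers(truth.age_range[0], truth.age_range[1] + 1, truth.n)
    sex = np.where(rng.random(truth.n) < 0.5, "F", "M")
    coverage = np.exp(rng.normal(truth.coverage_log_mean, truth.coverage_log_sd, truth.n))
    value = (
        truth.intercept
        + truth.slope * ages
        + truth.coverage_beta * coverage
        + truth.sex_beta * (sex == "M")
        + rng.normal(0, truth.noise_sd, truth.n)
    )
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(truth.n)],
            "age": ages,
            "sex": sex,
            "diagnosis": "CTRL",
            "mt_benchmark_coverage": coverage,
            truth.metric: value,
        }
    )
    from .stats import METRIC_COLUMNS

    for m in METRIC_COLUMNS:
        if m not in df.columns:
            df[m] = truth.intercept + rng.normal(0, truth.noise_sd, truth.n)
    return df


@dataclass(frozen=True)
class SpatialTruth:
    """Spatial section layout with layer-specific deletion-spot rates.

    Defaults emulate a cortical section: six imputed layers, grey-matter
    layers 3 and 5 enriched for deletion spots relative to white matter.
    """

    seed: int
    layers: tuple = ("L1", "L2+3", "L3", "L5", "L6", "WM")
    spots_per_layer: int = 2000
    deletion_spot_probs: dict = field(
        default_factory=lambda: {
            "L1": 0.015, "L2+3": 0.015, "L3": 0.03, "L5": 0.03, "L6": 0.015, "WM": 0.005,
        }
    )
    deletion_ids: tuple = ("6335-13999", "8471-13449")
    reads_per_spot: int = 3
    read_len: int = 91
    barcode_len: int = 16
    umi_len: int = 12


@dataclass
class SpatialData:
    read1: list[ReadRecord]
    read2: list[ReadRecord]
    whitelist: list[str]
    clusters: pd.DataFrame  # barcode, cluster
    ground_truth: pd.DataFrame  # barcode, layer
    truth_flags: pd.DataFrame  # barcode, layer, one bool column per deletion


def _index_barcode(i: int, length: int) -> str:
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(digits))


def simulate_spatial(
    ref: MitoReference, catalog: DeletionCatalog, truth: SpatialTruth
) -> SpatialData:
    """Simulate one spatial section.

    Spots are assigned to layers (clusters mirror layers one-to-one);
    deletion spots are drawn per layer probability independently for each
    catalog deletion in ``deletion_ids``, and each deletion spot emits at
    least one junction-spanning Read 2. Background Read 2 records are
    wild-type mitochondrial fragments. Read 1 carries the unique spot
    barcode followed by a random UMI.
    """
    rng = np.random.default_rng(truth.seed)
    del_ids = [d for d in truth.deletion_ids if d in set(catalog.ids)]
    windows: dict[str, tuple[str, list[int]]] = {}
    for did in del_ids:
        bp = catalog[did]
        genome = build_deleted_genome(ref, bp)
        starts = _valid_starts(genome, truth.read_len, (bp.primary_query, *bp.aux_queries))
        if not starts:
            raise ValueError(f"read_len {truth.read_len} too short to span {did} queries")
        windows[did] = (genome + genome[: truth.read_len - 1], starts)
    read1: list[ReadRecord] = []
    read2: list[ReadRecord] = []
    rows = []
    whitelist = []
    wt_doubled = ref.sequence + ref.sequence[: truth.read_len - 1]
    spot_i = read_i = 0
    for layer in truth.layers:
        p = truth.deletion_spot_probs.get(layer, 0.0)
        for _ in range(truth.spots_per_layer):
            barcode = _index_barcode(spot_i, truth.barcode_len)
            whitelist.append(barcode)
            flags = {did: bool(rng.random() < p) for did in del_ids}
            rows.append({"barcode": barcode, "layer": layer, **flags})
            seqs: list[str] = []
            for _ in range(truth.reads_per_spot):
                s = rng.integers(0, ref.length)
                seqs.append(wt_doubled[s : s + truth.read_len])
            for did, flagged in flags.items():
                if not flagged:
                    continue
                doubled, starts = windows[did]
                for _ in range(1 + rng.poisson(0.5)):
                    s = starts[rng.integers(0, len(starts))]
                    seqs.append(doubled[s : s + truth.read_len])
            for seq in seqs:
                rid = f"spatial:seed{truth.seed}:{read_i}"
                umi = "".join("ACGT"[b] for b in rng.integers(0, 4, truth.umi_len))
                read1.append(ReadRecord(rid, barcode + umi, mate=1))
                read2.append(ReadRecord(rid, seq, mate=2))
                read_i += 1
            spot_i += 1
    flags_df = pd.DataFrame(rows)
    clusters = pd.DataFrame(
        {"barcode": flags_df["barcode"], "cluster": flags_df["layer"]}
    )
    ground_truth = flags_df[["barcode", "layer"]].copy()
    return SpatialData(
        read1=read1,
        read2=read2,
        whitelist=whitelist,
        clusters=clusters,
        ground_truth=ground_truth,
        truth_flags=flags_df,
    )
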