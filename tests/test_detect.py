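"""Junction scanning, benchmark coverage, metrics, and split-read discovery."""

import gzip
import warnings

import numpy as np
import pytest

from mitodel import detect, refcat
from mitodel.detect import (
    FastqParseError,
    benchmark_coverage,
    compute_metrics,
    discover_junctions,
    read_fastq,
    reverse_complement,
    scan_reads,
)
from mitodel.refcat import DeletionBreakpoint, build_deleted_genome


def _pad(rng, core, left=30, right=30):
    bases = "ACGT"
    pre = "".join(bases[i] for i in rng.integers(0, 4, left))
    post = "".join(bases[i] for i in rng.integers(0, 4, right))
    return pre + core + post


class TestScanReads:
    def test_direct_containment_counts_one_deletion(self, catalog):
        rng = np.random.default_rng(0)
        read = _pad(rng, "CTCCGTAGACCTAACCTGAC")
        res = scan_reads([read], catalog)
        assert res.counts == {"6335-13999": 1, "7816-14807": 0, "8471-13449": 0}
        assert res.matched_read_ids["6335-13999"] == ["read0"]

    def test_aux_query_rule_blocks_primary_only(self, catalog):
        rng = np.random.default_rng(1)
        read = _pad(rng, "TCATCGACCTCCCCACCC")
        assert "ATCCTAGT" not in read and "GAAACTTCGG" not in read
        assert scan_reads([read], catalog).counts["7816-14807"] == 0

    def test_aux_query_rule_counts_full_junction_context(self, ref, catalog):
        bp = catalog["7816-14807"]
        genome = build_deleted_genome(ref, bp)
        # junction read spanning 7799..14847 in reference coordinates
        read = genome[7798 - 1 : 7798 - 1 + 100]
        assert scan_reads([read], catalog).counts["7816-14807"] == 1

    def test_wildtype_repeat_copy_not_counted(self, ref, catalog):
        # the 18-mer occurs verbatim in the wild-type reference at the 3'
        # repeat copy; the auxiliary 5'-side string must reject such reads
        wt = ref.fetch(14780, 14880)
        assert catalog["7816-14807"].primary_query in wt
        assert scan_reads([wt], catalog).counts["7816-14807"] == 0

    def test_matches_bruteforce_oracle_on_simulated_reads(self, ref, catalog):
        rng = np.random.default_rng(7)
        genome = build_deleted_genome(ref, catalog["8471-13449"])
        doubled = genome + genome[:99]
        reads = [doubled[s : s + 100] for s in rng.integers(0, len(genome), 1000)]
        res = scan_reads(reads, catalog)
        for bp in catalog:
            expected = sum(
                1
                for r in reads
                if all(q in r for q in (bp.primary_query, *bp.aux_queries))
            )
            assert res.counts[bp.id] == expected

    def test_read_counted_once_per_deletion(self, catalog):
        q = catalog["8471-13449"].primary_query
        read = q + "TTTT" + q  # two occurrences, one read
        assert scan_reads([read], catalog).counts["8471-13449"] == 1

    def test_orientation_both_detects_reverse_complement(self, catalog):
        rng = np.random.default_rng(2)
        read = reverse_complement(_pad(rng, catalog["8471-13449"].primary_query))
        assert scan_reads([read], catalog).counts["8471-13449"] == 0
        assert scan_reads([read], catalog, orientation="both").counts["8471-13449"] == 1


class TestBenchmarkCoverage:
    def test_single_window_read(self, ref):
        read = ref.fetch(*ref.benchmark_windows[0])
        assert benchmark_coverage([read], ref) == pytest.approx(250 / 500)

    def test_zero_reads_warns(self, ref):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            cov = benchmark_coverage([], ref)
        assert cov == 0.0 and any("empty" in str(x.message) for x in w)

    def test_uniform_reads_match_expected_depth(self, ref):
        rng = np.random.default_rng(11)
        n, rl = 10_000, 100
        doubled = ref.sequence + ref.sequence[: rl - 1]
        reads = [doubled[s : s + rl] for s in rng.integers(0, ref.length, n)]
        cov = benchmark_coverage(reads, ref)
        expect = n * rl / ref.length
        # binomial sampling of window overlap; conservative 3-SE band
        p = 500 / ref.length
        se = np.sqrt(n * p * (1 - p)) * rl / 500
        assert abs(cov - expect) < 3 * se

    def test_reverse_complement_reads_place(self, ref):
        read = reverse_complement(ref.fetch(*ref.benchmark_windows[0]))
        assert benchmark_coverage([read], ref) == pytest.approx(0.5)
        assert benchmark_coverage([read], ref, orientation="forward_only") == 0.0

    def test_origin_wrapping_read_places(self, ref):
        read = ref.fetch(ref.length - 49, ref.length) + ref.fetch(1, 50)
        assert benchmark_coverage([read], ref) == 0.0  # wraps, far from windows
        # and near window 1 via circular placement of a window-straddling read
        read2 = ref.fetch(601, 800)
        assert benchmark_coverage([read2], ref) == pytest.approx(100 / 500)

    def test_mismatch_tolerance(self, ref):
        read = list(ref.fetch(701, 800))
        read[10] = "A" if read[10] != "A" else "C"
        read = "".join(read)
        assert benchmark_coverage([read], ref, max_mismatches=0) == 0.0
        assert benchmark_coverage([read], ref, max_mismatches=2) == pytest.approx(100 / 500)


class TestComputeMetrics:
    def test_formula(self, catalog):
        m = compute_metrics({"8471-13449": 10}, 1000.0, 500, catalog)
        assert m.read_pct["8471-13449"] == pytest.approx(1.0)
        assert m.read_pct["6335-13999"] == 0.0

    def test_cumulative_scale_matches_published_regime(self, catalog):
        # 13 catalog reads at 56,577x coverage: cumulative ~0.023%, the
        # order of magnitude of a deep polyA bulk library
        m = compute_metrics({"8471-13449": 13}, 56_577.0, 10_000_000, catalog)
        assert m.cumulative_top_pct == pytest.approx(0.022978, abs=1e-4)

    def test_zero_coverage_missing_and_flagged(self, catalog):
        m = compute_metrics({"8471-13449": 2}, 0.0, 100, catalog)
        assert m.read_pct["8471-13449"] is None
        assert m.cumulative_top_pct is None
        assert m.inconsistent

    def test_zero_counts_zero_pct(self, catalog):
        m = compute_metrics({}, 500.0, 100, catalog)
        assert m.cumulative_top_pct == 0.0 and not m.inconsistent


class TestReadFastq:
    def test_roundtrip_plain_and_gz(self, tmp_path):
        recs = [("a/1 extra", "ACGT"), ("b/2", "GGCC")]
        for name in ("r.fastq", "r.fastq.gz"):
            path = tmp_path / name
            opener = gzip.open if name.endswith(".gz") else open
            with opener(path, "wt") as fh:
                for rid, seq in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            out = list(read_fastq(path))
            assert [r.sequence for r in out] == ["ACGT", "GGCC"]
            assert out[0].read_id == "a/1"  # comment stripped

    def test_truncated_gz_raises_with_location(self, tmp_path):
        good = tmp_path / "good.fastq.gz"
        with gzip.open(good, "wt") as fh:
            for i in range(50):
                fh.write(f"@r{i}\nACGTACGT\n+\nIIIIIIII\n")
        data = good.read_bytes()
        bad = tmp_path / "bad.fastq.gz"
        bad.write_bytes(data[: len(data) // 2])
        with pytest.raises(FastqParseError, match="bad.fastq.gz"):
            list(read_fastq(bad))


class TestDiscoverJunctions:
    def test_recovers_canonical_common_deletion(self, ref, catalog):
        genome = build_deleted_genome(ref, catalog["8471-13449"])
        reads = [genome[s : s + 100] for s in range(8471 - 80, 8471 - 20)]
        out = discover_junctions(reads, ref)
        assert out and out[0].b5 == 8482 and out[0].b3 == 13460
        assert out[0].support == len(reads)

    def test_wildtype_reads_yield_nothing(self, ref):
        reads = [ref.fetch(1000 + i, 1099 + i) for i in range(20)]
        assert discover_junctions(reads, ref) == []

    def test_toy_exhaustive_matches_bruteforce(self, toy_ref):
        """All 20-mers of a toy deleted genome vs brute-force enumeration
        of split placements (canonicalized and aggregated)."""
        ref = toy_ref
        bp = DeletionBreakpoint("d", 25, 36)  # 10 deleted bases
        genome = build_deleted_genome(ref, bp)
        reads = [genome[s : s + 20] for s in range(len(genome) - 19)]
        min_anchor = 8
        doubled = ref.sequence * 2
        expected: dict[tuple[int, int], int] = {}
        for read in reads:
            if read in doubled[: ref.length + len(read) - 1]:
                continue  # wild-type read: not split evidence
            junctions = set()
            for k in range(min_anchor, len(read) - min_anchor + 1):
                left, right = read[:k], read[k:]
                for p in range(ref.length):
                    if doubled[p : p + k] != left:
                        continue
                    for q in range(ref.length):
                        if doubled[q : q + len(right)] != right:
                            continue
                        b5, b3 = p + k, q + 1
                        if b3 > b5 + 1:
                            cand = DeletionBreakpoint("c", b5, b3)
                            junctions.add(refcat.adjust_breakpoint(ref, cand)[:2])
            assert len(junctions) <= 1, "toy genome should be unambiguous"
            for j in junctions:
                expected[j] = expected.get(j, 0) + 1
        got = {(j.b5, j.b3): j.support for j in discover_junctions(reads, ref, min_anchor)}
        assert got == expected
        assert sum(expected.values()) > 0  # the junction is actually exercised
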