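# Methods

## Coordinate and naming conventions

All genomic coordinates are 1-based and inclusive on the 16,569-bp
human mitochondrial reference frame (rCRS numbering). A deletion is the
pair (b5, b3) with b5 the last retained base 5′ of the junction and b3
the first retained base 3′ of it; the deleted span is b3 − b5 − 1. This
is the unique convention under which the 8471-13449 breakpoint pair
yields the canonical 4977-bp common deletion.

### Direct-repeat ambiguity and canonical placement

mtDNA deletions form between direct repeats, so a deleted molecule's
junction can be written at any placement (p, q) with q − p = b3 − b5
whose deleted genome is byte-identical. `adjust_breakpoint` enumerates
this equivalence class by sliding the junction one base at a time
(a shift left is valid iff ref[b5] == ref[b3 − 1], right iff
ref[b5 + 1] == ref[b3]) and reports `repeat_len` = class size − 1. The
canonical placement is the **3′-most** member (config constant
`CANONICAL_PLACEMENT = "three_prime"`): the deletion is named with the
repeat copy retained on the 5′ side. This convention is idempotent and
reproduces the conventional adjusted anchors 6341-14005 (for 6335-13999,
11-bp repeat) and 8482-13460 (for 8471-13449, 13-bp repeat).

The third catalog entry, 7816-14807, is conventionally quoted with the
adjusted pair 7814-14805 — two bases 5′ of the raw placement. That
anchor cannot be produced by perfect-repeat sliding under any idempotent
convention: the raw placement always belongs to its own equivalence
class, so a fixed choice function can only return placements 5′ of raw
for every deletion or 3′ of raw for every deletion, never both
directions across the catalog. On the rCRS frame the perfect-equivalence
class of 7816-14807 spans placements 7808–7821 (the 8-bp repeat TCATCGAC
extended by coincidental CTCCC homology), and the 3′-most rule yields
7821-14812. The 7814-14805 label evidently derives from an
imperfect-repeat (alignment-based) treatment; imperfect-repeat
adjustment is out of scope here, and the corresponding acceptance test
records this one pair as an expected failure. All placements of a given
deletion describe the same molecule, so downstream counts are unaffected
by the naming.

## Vendored reference

`data/mito_reference_synthetic.fa` is a **synthetic stand-in** for the
rCRS (NC_012920.1), which could not be redistributed here. It is derived
from a closely related public human mitochondrial genome record
(16,571 bp) by normalizing the control-region and placeholder indels to
the rCRS coordinate frame (two poly-C bases removed near position 310,
the placeholder N inserted at 3107, one poly-C base removed near 16184)
and correcting position 7815 to A as required by the published junction
context of the 7816-14807 deletion. All three catalog junction strings,
the unique (8, 10) flank split of the 18-mer TCATCGACCTCCCCACCC, the
auxiliary strings ATCCTAGT (7799-7806) and GAAACTTCGG (14838-14847), and
the repeat structures of the 6335/8471 junctions verify against it at
rCRS coordinates. Outside the junction neighborhoods the sequence may
differ from the rCRS at scattered positions; analyses of real data
should substitute the true NC_012920.1 record via `load_reference`.

## Detection

Scanning follows the operational definition of junction support: exact
substring containment of the primary query, plus containment of every
auxiliary query, all on the same strand. The default orientation is
forward-only (mirroring a literal grep over FASTQ); both-strand scanning
is a flag. The auxiliary-query rule exists because a junction query can
occur verbatim in the unbroken genome when the junction lies inside a
repeat: the 18-mer of 7816-14807 appears at 14799-14816 of the wild-type
sequence, so the 5′-side string ATCCTAGT (and 3′-side GAAACTTCGG) must
co-occur in the read to certify a junction. Counting is per read, not
per pair — both mates matching counts twice, as grep over split files
would — and mismatch tolerance defaults to 0.

**Benchmark coverage** is the mean depth over two equal-width 250-bp
windows placed inside RNR1 and CYB (defaults 701-950 and 15101-15350;
the window placement is a configurable pipeline choice, not a catalog
property). Each read is placed at its best exact (or ≤ max_mismatches)
position on the circular reference — circularity handled by doubling the
reference string — preferring forward placements and, among ties, the
smallest coordinate; reads that do not place contribute nothing.
Coverage = total read bases overlapping the windows / total window
width. The deletion read % is 100 × count / coverage, reported missing
when coverage is zero (and flagged inconsistent if counts are nonzero).
The cumulative metric sums the catalog's `top_n` entries (the shipped
catalog has three; the historical catalog this mirrors has thirty).

**Split-read discovery** (`discover_junctions`) is a deliberately simple
stand-in for alignment-based breakpoint callers, for error-free or
low-error reads: the longest exact prefix and suffix of each read are
anchored on the circular reference; when both anchors reach
`min_anchor` (default 20) bases and jointly cover the read, the implied
junction is taken at the maximal-prefix split and canonicalized, so all
repeat-equivalent splits aggregate. It makes no attempt at mismatch
tolerance, multi-deletion phasing, or duplication breakpoints.

## Statistics

Implementations delegate to scipy/statsmodels: Spearman (average ranks
on ties) and Pearson with two-sided p-values; Welch's t
(`equal_var=False`), with the degenerate all-constant case reported as
t = 0, p = 1; OLS with treatment-coded categoricals (alphabetical
reference level) and rank-deficiency detection that names the collinear
columns; one-factor repeated-measures ANOVA (listwise removal of
incomplete subjects; with two levels F equals the squared paired t);
pooled-variance two-proportion Z-tests. The Bonferroni family is fixed
at m = 4 — the three named deletions plus the cumulative metric — which
is the family jointly tested in the designs this package targets.
Spearman p-values use the t approximation at all n (R's cor.test reports
exact permutation values below n = 1290; the difference is negligible at
cohort sizes and the statistic itself is identical). Fold differences
default to the ratio of arithmetic means, with median-ratio and
geometric-mean options, since conventions differ between studies.

## Spatial analysis

Read 1 of a Visium-style pair carries the spot barcode (first 16 nt by
default) and a 12-nt UMI; read ids are normalized by stripping comments
and /1, /2 suffixes so mates cross-reference. A spot is a "deletion
spot" for a catalog entry when at least one of its Read 2 sequences
passes the same containment rule as bulk scanning; flags are boolean per
spot, which makes the result invariant to UMI duplication (so no UMI
deduplication is performed). Junction reads with non-whitelisted
barcodes are discarded and counted.

Cluster-to-layer imputation computes, on the intersection of the
cluster and ground-truth barcode universes, the proportion of each
cluster's spots in each annotated layer. A cluster is assigned to its
best layer only when that overlap is **strictly greater than 40%**, and
clusters with overall frequency **below 5%** are never assigned; several
clusters may map to one layer, and unassigned clusters are excluded from
layer tests rather than pooled. Per-layer deletion-spot proportions are
compared pairwise with pooled two-proportion Z-tests; multi-section
studies pool by summing numerators and denominators before testing.
Compact significance letters are built by insert-and-absorb, so two
layers share a letter iff they do not differ at alpha.

## Synthetic data

Generators are pure functions of (parameters, seed) via a single
`numpy.random.default_rng` stream per call; the seed is recorded in
every read header, and identical seeds give byte-identical FASTQ.

- **Bulk libraries**: each read is a uniform draw from the circular
  wild-type genome, from a deleted genome (per-deletion
  `junction_fractions`, shares of mitochondrial reads), or a uniform
  random decoy standing in for the non-mitochondrial background (a real
  nuclear genome is deliberately not used: nuclear pre-filtering is
  immaterial to junction counting, and random decoys keep the package
  self-contained). Substitution errors are applied per base at
  `error_rate` (default 0); no quality-score, PCR-duplicate, or indel
  error modeling. Defaults: 100k reads of 100 nt, 20% mitochondrial.
- **Paired platforms**: per-sample latent burdens are lognormal; the
  DNA value is `fold_factor` × latent × lognormal noise and the RNA
  value latent × noise. Defaults — 30 matched samples, fold 22, noise
  SD 0.5 on the log scale — mirror the matched-cohort design and the
  published DNA/RNA offset for the common deletion; the noise level is
  set so rank correlations land in the moderate, realistic range.
- **Age cohorts**: metric = intercept + slope × age + coverage and sex
  effects + Gaussian noise, ages uniform on 20–96. The default slope
  (0.005 %/yr on a baseline near 0.05–0.5) gives the clearly positive
  but noisy age trend typical of brain and muscle cohorts; the two
  junctions that show no age effect in such cohorts get slope 0.
- **Spatial sections**: six layers (L1, L2+3, L3, L5, L6, WM) with 2000
  spots each by default; deletion spots drawn per layer with defaults
  3% in L3/L5, 0.5% in WM, 1.5% elsewhere — the grey-versus-white
  contrast the layer tests are designed to detect. Every deletion spot
  emits at least one junction read (1 + Poisson(0.5)); background reads
  are wild-type 91-mers; barcodes are unique by construction, and
  clusters mirror layers one-to-one (messier cluster/ground-truth
  geometries are exercised directly in tests).

What passing on these generators shows — and what it does not: the
detectors are exact on error-free reads and counts recover planted
fractions within binomial error, but real libraries add sequencing
error, strand mixtures, alignment-filter interactions, transcript-
abundance structure along the genome, and NUMT-derived reads, none of
which the generators model. Recovery on synthetic data validates the
pipeline's arithmetic, not the biological detectability of deletions in
any particular real library.

## Numerical and scale choices

Exact string placement makes detection and coverage deterministic;
ambiguous placements tie-break to the smallest coordinate, and forward
placement is preferred over reverse-complement. Mismatch-tolerant
placement is a simple O(L·n) scan intended for small inputs. Validation
suites run at reduced but statistically meaningful sizes — 100k-read
recovery checks, 100-replicate CI coverage, 20-replicate spatial power
at 2000 spots/layer — chosen so the full suite completes in a few
minutes while keeping each check's sampling error well below its
tolerance (recovery bands are 3 SE; power checks have true power ≈ 1 at
the planted effects).

## Known limitations

- Imperfect-repeat breakpoint adjustment is not implemented (see above).
- No BLAST-style fuzzy junction matching: queries are exact substrings,
  so heavily errored junction reads are missed.
- Deletions spanning the replication origin (b3 < b5 on the circle) are
  not represented.
- The spatial path consumes cluster assignments; it does not cluster
  expression data itself.
- The vendored reference is a labelled synthetic stand-in; real-data
  runs should supply the true rCRS record.
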