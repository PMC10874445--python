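"""Catalog-free junction discovery from split reads.

Simulates reads straddling the common-deletion junction and recovers the
breakpoint without being told where it is. Discovered junctions are
reported at their canonical (3'-most) placement, so the raw 8471-13449
junction surfaces as 8482-13460 — the two name the same deleted molecule,
the junction having slid along the 13-bp flanking direct repeat.
"""

from mitodel import build_deleted_genome, default_catalog, default_reference, detect

ref = default_reference()
catalog = default_catalog(ref)

genome = build_deleted_genome(ref, catalog["8471-13449"])
# reads whose 100-mers cross the junction with at least 20-base anchors
reads = [genome[start : start + 100] for start in range(8471 - 75, 8471 - 25)]

for j in detect.discover_junctions(reads, ref, min_anchor=20):
    print(f"junction {j.b5}-{j.b3}  supporting reads: {j.support}")
    print(f"deleted bases: {j.b3 - j.b5 - 1}")
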