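"""Detect broken gene-order adjacencies around a focal gene.

Compares the conserved 11-gene avian order around the focal locus with (a) a
bird-like query that retains it and (b) a rodent-like query in which the
region was scattered across chromosomes.
"""

from genedecay.event_inference import GeneOrder, detect_breakpoints

REFERENCE = GeneOrder(
    "reference",
    ("BLVRA", "VOPP1", "LANCL2", "EGFR", "SEC61G", "COA1",
     "STK17A", "HECW1", "MRPL32", "PSMA2", "C7orf25"),
)

bird = GeneOrder("bird", REFERENCE.genes)
report = detect_breakpoints(REFERENCE, bird)
print(f"bird: {len(report.broken_adjacencies)} broken adjacencies "
      f"(conserved order)")

scattered = GeneOrder(
    "post_rearrangement",
    ("BLVRA", "VOPP1", "LANCL2", "EGFR", "SEC61G",
     "HECW1", "MRPL32", "PSMA2", "C7orf25", "STK17A"),
    chromosomes=("chr2",) * 5 + ("chr4",) * 4 + ("chr11",),
)
report = detect_breakpoints(REFERENCE, scattered)
print(f"post-rearrangement: {len(report.broken_adjacencies)} broken adjacencies, "
      f"missing genes: {report.missing_genes}")
for run, chrom in report.moved_segments:
    print(f"  moved segment {'-'.join(run)} -> {chrom}")

# The focal gene is gone and its flanks sit on different chromosomes: the
# signature of a gene loss co-occurring with an evolutionary breakpoint.
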