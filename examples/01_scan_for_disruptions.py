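"""Scan an observed gene copy against its intact reference.

Builds the feliform worked example (a synthetic four-exon gene carrying the
cheetah's catalogued C->T substitution at exon-2 base 27), scans it, and
prints the recovered mutations and premature stop codons.
"""

from genedecay.gene_models import scan_disruptions
from genedecay.synthetic_data import make_fixture

fixture = make_fixture("cheetah")
report = scan_disruptions(
    fixture.reference, fixture.observed_gene("Acinonyx_jubatus")
)

print(f"species: {report.species}")
print(f"status:  {report.status.value}")
for m in report.mutations_detected:
    print(f"  mutation: {m.kind} at exon-{m.exon} base {m.position} "
          f"(length {m.length}{', alt ' + m.alt if m.alt else ''})")
for exon, base, codon in report.premature_stops:
    print(f"  premature stop: {codon} at exon-{exon}, codon starting base {base}")
print(f"terminal frame offset: {report.terminal_frame_offset}")

# The single C->T substitution converts an in-frame CAA codon to TAA: one
# premature stop, no frameshift, status 'disrupted'.
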