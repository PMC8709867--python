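"""Regenerate the versioned fixtures/ directory from the fixture builders.

Each fixture directory holds the intact reference plus observed gene copies
(exon-tagged FASTA), the mutation catalog (TSV), the time tree (Newick) and
the expected outcomes (JSON).  Run from the repository root:

    python scripts/export_fixtures.py
"""

import json
from dataclasses import replace
from pathlib import Path

from genedecay import io as gdio
from genedecay.synthetic_data import make_fixture

ROOT = Path(__file__).resolve().parents[1]

for name in ("galliform", "rodent", "sciuridae", "cheetah"):
    fixture = make_fixture(name)
    out = ROOT / "fixtures" / name
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(fixture.newick + "\n")
    genes = [fixture.reference]
    genes += [fixture.observed_gene(sp) for sp in fixture.expected_disrupted]
    genes += [replace(fixture.reference, species=sp) for sp in fixture.intact_species]
    gdio.write_exon_fasta(genes, out / "sequences.fasta")
    gdio.write_catalog_tsv(fixture.catalogs, out / "catalog.tsv")
    if fixture.duplicate_copies:
        gdio.write_catalog_tsv(fixture.duplicate_copies, out / "duplicate_copy_catalog.tsv")
    gdio.write_json(
        {
            "expected_events": fixture.expected_events,
            "expected_disrupted": fixture.expected_disrupted,
            "intact_species": fixture.intact_species,
            "putative_losses": list(fixture.putative_losses),
        },
        out / "expected.json",
    )
    print(f"wrote fixtures/{name}")
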