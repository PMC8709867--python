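"""Readers and writers for the package's on-disk formats.

Formats are deliberately plain: exon-tagged FASTA (headers
``species|gene|exonN|phaseP``), tab-separated mutation catalogs and trait
tables, Newick trees, and JSON reports.  Catalog TSVs round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from genedecay.event_inference import GeneOrder, LossEvent
from genedecay.gene_models import ExonModel, GeneModel, MutationRecord

CATALOG_COLUMNS = ["species", "exon", "kind", "anchor_unit", "position", "length", "alt"]


# -- exon FASTA -------------------------------------------------------------


def write_exon_fasta(genes: Iterable[GeneModel], path) -> None:
    records = []
    for gene in genes:
        for exon in gene.exons:
            header = f"{gene.species}|{gene.gene}|exon{exon.index}|phase{exon.phase}"
            records.append(SeqRecord(Seq(exon.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_exon_fasta(path) -> dict[tuple[str, str], GeneModel]:
    """Returns {(species, gene): GeneModel}; exons ordered by their index."""
    exons: dict[tuple[str, str], list[ExonModel]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 4 or not parts[2].startswith("exon"):
            raise ValueError(f"malformed exon FASTA header {record.id!r}")
        species, gene = parts[0], parts[1]
        index = int(parts[2][4:])
        phase = int(parts[3][5:])
        exons.setdefault((species, gene), []).append(
            ExonModel(index=index, sequence=str(record.seq).upper(), phase=phase)
        )
    out = {}
    for key, exon_list in exons.items():
        exon_list.sort(key=lambda e: e.index)
        out[key] = GeneModel(species=key[0], gene=key[1], exons=tuple(exon_list))
    return out


def read_spliced_fasta(path, exon_lengths_tsv) -> dict[tuple[str, str], GeneModel]:
    """Spliced-CDS FASTA (headers ``species|gene``) with a sidecar TSV of exon
    lengths (columns: gene, exon, length) shared by all species."""
    lengths = pd.read_csv(exon_lengths_tsv, sep="\t")
    by_gene: dict[str, list[int]] = {}
    for _, row in lengths.sort_values(["gene", "exon"]).iterrows():
        by_gene.setdefault(str(row["gene"]), []).append(int(row["length"]))
    out = {}
    for record in SeqIO.parse(str(path), "fasta"):
        species, gene = record.id.split("|")[:2]
        seq = str(record.seq).upper()
        cuts = by_gene[gene]
        if sum(cuts) != len(seq):
            raise ValueError(f"{record.id}: exon lengths do not sum to CDS length")
        pieces, start = [], 0
        for L in cuts:
            pieces.append(seq[start : start + L])
            start += L
        out[(species, gene)] = GeneModel.from_sequences(species, gene, pieces)
    return out


# -- codon alignments -------------------------------------------------------


def read_phylip_sequential(path) -> dict[str, str]:
    """Sequential (non-interleaved) PHYLIP with relaxed names: header line
    ``ntaxa nchar``, then one ``name  sequence`` record per taxon (the
    sequence may wrap onto following lines)."""
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    ntaxa, nchar = (int(x) for x in lines[0].split()[:2])
    sequences: dict[str, str] = {}
    name = None
    for line in lines[1:]:
        if name is None or len(sequences[name]) >= nchar:
            parts = line.split(None, 1)
            name = parts[0]
            sequences[name] = parts[1].replace(" ", "") if len(parts) > 1 else ""
        else:
            sequences[name] += line.replace(" ", "")
    if len(sequences) != ntaxa or any(len(s) != nchar for s in sequences.values()):
        raise ValueError("malformed sequential PHYLIP file")
    return sequences


def write_phylip_sequential(sequences: Mapping[str, str], path) -> None:
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("all sequences must have equal length")
    (nchar,) = lengths
    with open(path, "w") as fh:
        fh.write(f" {len(sequences)} {nchar}\n")
        for name in sequences:
            fh.write(f"{name}  {sequences[name]}\n")


def params_to_json(params, path=None):
    """Serialize fitted codon-model parameters (branch keys become sorted
    comma-joined leaf lists)."""
    payload = {
        "kappa": params.kappa,
        "omega_by_category": dict(params.omega_by_category),
        "pi": [float(x) for x in params.pi],
        "branch_lengths": {
            ",".join(sorted(key)): float(t) for key, t in params.branch_lengths.items()
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def read_category_map_tsv(path) -> dict:
    """Branch-category TSV: columns ``branch`` (comma-joined leaf labels
    below the branch) and ``category``."""
    table = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    return {
        frozenset(row["branch"].split(",")): row["category"]
        for _, row in table.iterrows()
    }


# -- mutation catalogs ------------------------------------------------------


def write_catalog_tsv(catalogs: Mapping[str, Iterable[MutationRecord]], path) -> None:
    rows = [
        {
            "species": m.species,
            "exon": m.exon,
            "kind": m.kind,
            "anchor_unit": m.anchor_unit,
            "position": m.position,
            "length": m.length,
            "alt": m.alt,
        }
        for species in sorted(catalogs)
        for m in catalogs[species]
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> dict[str, list[MutationRecord]]:
    table = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    catalogs: dict[str, list[MutationRecord]] = {}
    for _, row in table.iterrows():
        record = MutationRecord(
            species=row["species"],
            exon=int(row["exon"]),
            kind=row["kind"],
            anchor_unit=row["anchor_unit"],
            position=int(row["position"]),
            length=int(row["length"]),
            alt=row["alt"],
        )
        catalogs.setdefault(record.species, []).append(record)
    return catalogs


# -- gene orders ------------------------------------------------------------


def read_gene_orders_tsv(path) -> dict[str, GeneOrder]:
    table = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    orders = {}
    for species, group in table.groupby("species", sort=True):
        group = group.copy()
        group["rank"] = group["rank"].astype(int)
        group = group.sort_values("rank")
        orders[species] = GeneOrder(
            species=species,
            genes=tuple(group["gene"]),
            strands=tuple(group.get("strand", "?")),
            chromosomes=tuple(group.get("chromosome", "")),
        )
    return orders


def write_gene_orders_tsv(orders: Mapping[str, GeneOrder], path) -> None:
    rows = []
    for species in sorted(orders):
        order = orders[species]
        for rank, (gene, strand, chrom) in enumerate(
            zip(order.genes, order.strands, order.chromosomes), 1
        ):
            rows.append(
                {
                    "species": species,
                    "rank": rank,
                    "gene": gene,
                    "strand": strand,
                    "chromosome": "" if chrom is None else chrom,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- traits -----------------------------------------------------------------


def read_trait_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"species", "retention", "white_pct", "pink_pct", "red_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns {sorted(missing)}")
    total = table[["white_pct", "pink_pct", "red_pct"]].sum(axis=1)
    bad = table.loc[(total - 100).abs() > 0.5, "species"]
    if len(bad):
        raise ValueError(f"fiber percentages do not sum to 100: {list(bad)}")
    return table


def write_trait_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- JSON reports -----------------------------------------------------------


def _branch_repr(branch) -> list:
    return sorted(branch)


def events_to_json(events: Iterable[LossEvent], path=None):
    payload = [
        {
            "event_id": e.event_id,
            "species": sorted(e.species),
            "branch": _branch_repr(e.branch),
            "homoplastic": e.homoplastic,
            "n_shared_mutations": len(e.shared_mutations),
            "n_private_mutations": len(e.private_mutations),
        }
        for e in events
    ]
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
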