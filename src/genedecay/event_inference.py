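"""Loss-event inference on time-calibrated trees and gene-order breakpoints.

Species whose gene copies share an identical inactivating mutation are taken
to descend from a single loss event (Dollo parsimony: one origin, no regain).
Each event is assigned to the stem branch of the sharing clade, that branch is
labeled *mixed* (the gene was functional for part of it and pseudogenic for
the rest), every branch below it *pseudogenic*, and all others *functional*.
The module also detects broken gene-order adjacencies between a reference and
a query region — the signal used to recognise evolutionary breakpoint
regions around a focal gene.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from genedecay.gene_models import GeneModel, MutationRecord, resolve_record

FUNCTIONAL = "functional"
MIXED = "mixed"
PSEUDOGENIC = "pseudogenic"

BranchKey = frozenset  # frozenset of leaf labels below the branch's child


class StatusTree:
    """A rooted ultrametric tree with ages in MY and per-branch status labels.

    Branches are identified by the set of leaf labels below their child node.
    All branches start out ``functional``.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        rel_tol: float = 1e-6,
        require_ultrametric: bool = True,
    ):
        self._tree = tree
        tree.encode_bipartitions()
        self._ages: dict[dendropy.Node, float] = {}
        self._require_ultrametric = require_ultrametric
        self._compute_ages(rel_tol if require_ultrametric else float("inf"))
        self.labels: dict[BranchKey, str] = {
            self.branch_key(node): FUNCTIONAL
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
        }

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, require_ultrametric: bool = True) -> "StatusTree":
        """Parse a rooted Newick tree with branch lengths in MY.

        ``require_ultrametric=False`` admits non-clock trees (useful for
        trait work, where only patristic distances matter); ages are then
        nominal.
        """
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls(tree, require_ultrametric=require_ultrametric)

    def _compute_ages(self, rel_tol: float) -> None:
        # leaf ages are 0; parent age = child age + branch length, checked for
        # consistency across children (ultrametricity)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._ages[node] = 0.0
            else:
                ages = [
                    self._ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
                ]
                span = max(ages) - min(ages)
                if span > rel_tol * max(max(ages), 1.0):
                    raise ValueError(
                        f"tree is not ultrametric: node ages disagree by {span:g} MY"
                    )
                self._ages[node] = sum(ages) / len(ages)
        if rel_tol != float("inf"):
            for node in self._tree.preorder_node_iter():
                if node.parent_node is not None:
                    if self._ages[node.parent_node] <= self._ages[node]:
                        raise ValueError("parent age must exceed child age")

    # -- branch bookkeeping -------------------------------------------------

    def branch_key(self, node: dendropy.Node) -> BranchKey:
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())

    @property
    def root_age(self) -> float:
        return self._ages[self._tree.seed_node]

    @property
    def leaf_labels(self) -> frozenset:
        return self.branch_key(self._tree.seed_node)

    def branches(self) -> list[BranchKey]:
        return list(self.labels)

    def node_for(self, key: BranchKey) -> dendropy.Node:
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None and self.branch_key(node) == key:
                return node
        raise KeyError(f"no branch with leaf set {sorted(key)}")

    def branch_duration(self, key: BranchKey) -> float:
        node = self.node_for(key)
        return self._ages[node.parent_node] - self._ages[node]

    def child_age(self, key: BranchKey) -> float:
        return self._ages[self.node_for(key)]

    def mrca_branch(self, species: Iterable[str]) -> BranchKey:
        """Branch key of the stem branch of the MRCA of ``species``.

        For the whole leaf set this would be the root, which has no stem; that
        case raises.
        """
        taxa = set(species)
        node = self._tree.mrca(taxon_labels=taxa)
        if node.parent_node is None:
            raise ValueError("MRCA of the species set is the root; no stem branch")
        return self.branch_key(node)

    def descendant_branches(self, key: BranchKey) -> list[BranchKey]:
        node = self.node_for(key)
        return [
            self.branch_key(n)
            for n in node.preorder_iter()
            if n is not node and n.parent_node is not None
        ]

    def is_clade(self, species: Iterable[str]) -> bool:
        taxa = set(species)
        if len(taxa) == 1:
            return True
        node = self._tree.mrca(taxon_labels=taxa)
        return self.branch_key(node) == frozenset(taxa)

    def copy(self) -> "StatusTree":
        clone = StatusTree(
            self._tree.clone(depth=1),
            require_ultrametric=self._require_ultrametric,
        )
        clone.labels = dict(self.labels)
        return clone

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


@dataclass
class LossEvent:
    """One independent gene-inactivation event."""

    event_id: str
    species: frozenset
    branch: BranchKey
    shared_mutations: list[MutationRecord] = field(default_factory=list)
    private_mutations: list[MutationRecord] = field(default_factory=list)
    homoplastic: bool = False


# ---------------------------------------------------------------------------
# mutation identity across species
# ---------------------------------------------------------------------------


def _key(m: MutationRecord) -> tuple:
    return (m.exon, m.kind, m.position, m.length, m.alt)


def records_match(a: MutationRecord, b: MutationRecord) -> bool:
    """Identical resolved coordinates/length/alt, or containment.

    Containment covers post-loss extension of a shared indel in one lineage
    (e.g. a shared 2-base insertion later extended to 5 bases): a record of
    the same kind, exon and anchor whose edit contains the other's counts as
    the shared mutation plus a private extension.
    """
    if a.exon != b.exon or a.kind != b.kind:
        return False
    if _key(a) == _key(b):
        return True
    if a.kind == "deletion":
        lo_a, hi_a = a.position, a.position + a.length - 1
        lo_b, hi_b = b.position, b.position + b.length - 1
        return (lo_a <= lo_b and hi_b <= hi_a) or (lo_b <= lo_a and hi_a <= hi_b)
    if a.kind == "insertion":
        if a.position != b.position:
            return False
        return a.alt in b.alt or b.alt in a.alt
    return False


def infer_loss_events(
    tree: StatusTree,
    catalogs: Mapping[str, Iterable[MutationRecord]],
    reference: GeneModel | None = None,
) -> list[LossEvent]:
    """Cluster per-species disruptions into independent loss events.

    Species sharing at least one matching mutation are grouped (transitively);
    each group's event is assigned to the stem branch of the group's MRCA
    (terminal branch for singletons).  A shared mutation across a
    non-monophyletic species set is still assigned to the MRCA stem but the
    event is flagged homoplastic, never silently split.
    """
    resolved: dict[str, list[MutationRecord]] = {}
    for sp, records in catalogs.items():
        recs = list(records)
        if any(r.anchor_unit == "codon" for r in recs) and reference is None:
            raise ValueError("codon-anchored records require a reference gene model")
        resolved[sp] = [
            resolve_record(r, reference) if r.anchor_unit == "codon" else r for r in recs
        ]
    disrupted = sorted(sp for sp, recs in resolved.items() if recs)
    missing = set(disrupted) - set(tree.leaf_labels)
    if missing:
        raise ValueError(f"catalog species not on the tree: {sorted(missing)}")

    # union-find over species sharing a matching mutation
    parent = {sp: sp for sp in disrupted}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for sa, sb in itertools.combinations(disrupted, 2):
        if any(
            records_match(ma, mb)
            for ma in resolved[sa]
            for mb in resolved[sb]
        ):
            union(sa, sb)

    groups: dict[str, list[str]] = {}
    for sp in disrupted:
        groups.setdefault(find(sp), []).append(sp)

    events = []
    for members in sorted(groups.values(), key=lambda g: sorted(g)[0]):
        species = frozenset(members)
        if len(members) == 1:
            branch = frozenset(members)
            homoplastic = False
        else:
            branch = tree.mrca_branch(members)
            homoplastic = not tree.is_clade(members)
        shared, private = _split_shared_private(resolved, members)
        events.append(
            LossEvent(
                event_id="",
                species=species,
                branch=branch,
                shared_mutations=shared,
                private_mutations=private,
                homoplastic=homoplastic,
            )
        )
    events.sort(key=lambda e: sorted(e.species)[0])
    for i, event in enumerate(events, 1):
        event.event_id = f"loss_{i:02d}"
    return events


def _split_shared_private(
    resolved: Mapping[str, list[MutationRecord]], members: list[str]
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    shared: list[MutationRecord] = []
    private: list[MutationRecord] = []
    for sp in members:
        for m in resolved[sp]:
            others = [o for o in members if o != sp]
            if others and any(
                records_match(m, mo) for o in others for mo in resolved[o]
            ):
                if not any(_key(m) == _key(s) for s in shared):
                    shared.append(m)
            else:
                private.append(m)
    return shared, private


def label_branches(tree: StatusTree, events: Iterable[LossEvent]) -> StatusTree:
    """Return a copy of ``tree`` with event branches mixed and descendants pseudogenic.

    Two events nested on the same root-to-leaf path are an error: under Dollo
    parsimony a lineage cannot lose the gene twice.
    """
    out = tree.copy()
    events = list(events)
    keys = [e.branch for e in events]
    for a, b in itertools.combinations(keys, 2):
        if a < b or b < a:  # proper subset = nested on one path
            raise ValueError(
                f"nested loss events on one lineage: {sorted(a)} within {sorted(b)}"
            )
    for key in out.labels:
        out.labels[key] = FUNCTIONAL
    for event in events:
        if event.branch not in out.labels:
            raise ValueError(f"event branch {sorted(event.branch)} not in tree")
        out.labels[event.branch] = MIXED
        for desc in out.descendant_branches(event.branch):
            out.labels[desc] = PSEUDOGENIC
    return out


# ---------------------------------------------------------------------------
# gene-order breakpoints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneOrder:
    """An ordered list of signed gene symbols around a focal gene."""

    species: str
    genes: tuple[str, ...]
    strands: tuple[str, ...] = ()  # '+', '-', or '?' per gene; ignored for adjacency
    chromosomes: tuple = ()  # optional chromosome/scaffold per gene

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "strands", tuple(self.strands) or ("?",) * len(self.genes))
        object.__setattr__(
            self, "chromosomes", tuple(self.chromosomes) or (None,) * len(self.genes)
        )
        seen = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"duplicate gene symbol {g!r} in {self.species}")
            seen.add(g)

    def chromosome_of(self, gene: str) -> object:
        return self.chromosomes[self.genes.index(gene)]


@dataclass
class BreakpointReport:
    """Adjacency-level comparison of a query gene order against a reference."""

    broken_adjacencies: list[tuple[str, str]]
    missing_genes: list[str]
    moved_segments: list[tuple[tuple[str, ...], object]]  # (run, query chromosome)
    retained_runs: list[tuple[tuple[str, ...], object]]


def detect_breakpoints(reference: GeneOrder, query: GeneOrder) -> BreakpointReport:
    """Report reference adjacencies broken in the query.

    A reference adjacency (a, b) is retained iff a and b are adjacent in the
    query, in either order, on the same chromosome.  Maximal retained runs are
    reported with their query chromosome; runs lying on a different query
    chromosome than the run containing the first reference gene are flagged as
    moved segments.
    """
    q_index = {g: i for i, g in enumerate(query.genes)}
    missing = [g for g in reference.genes if g not in q_index]

    def retained(a: str, b: str) -> bool:
        if a not in q_index or b not in q_index:
            return False
        if abs(q_index[a] - q_index[b]) != 1:
            return False
        return query.chromosome_of(a) == query.chromosome_of(b)

    broken = [
        (a, b)
        for a, b in zip(reference.genes, reference.genes[1:])
        if not retained(a, b)
    ]

    runs: list[tuple[tuple[str, ...], object]] = []
    current = [reference.genes[0]] if reference.genes else []
    for a, b in zip(reference.genes, reference.genes[1:]):
        if retained(a, b):
            current.append(b)
        else:
            runs.append(tuple(current))
            current = [b]
    if current:
        runs.append(tuple(current))
    located = [
        (run, query.chromosome_of(run[0]) if run[0] in q_index else None)
        for run in runs
        if any(g in q_index for g in run)
    ]
    anchor_chrom = located[0][1] if located else None
    moved = [(run, chrom) for run, chrom in located[1:] if chrom != anchor_chrom]
    return BreakpointReport(
        broken_adjacencies=broken,
        missing_genes=missing,
        moved_segments=moved,
        retained_runs=located,
    )
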