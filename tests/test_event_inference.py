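"""Loss-event clustering, branch labeling and gene-order breakpoints."""

import numpy as np
import pytest

from genedecay.event_inference import (
    FUNCTIONAL,
    MIXED,
    PSEUDOGENIC,
    GeneOrder,
    LossEvent,
    StatusTree,
    detect_breakpoints,
    infer_loss_events,
    label_branches,
    records_match,
)
from genedecay.gene_models import MutationRecord


def _mut(species, exon=1, kind="deletion", position=10, length=1, alt=""):
    return MutationRecord(
        species=species, exon=exon, kind=kind, position=position, length=length, alt=alt
    )


@pytest.fixture
def quartet():
    return StatusTree.from_newick("((A:10,B:10):10,(C:15,D:15):5);")


class TestStatusTree:
    def test_ages_and_durations(self, quartet):
        assert quartet.root_age == pytest.approx(20.0)
        ab = frozenset("AB")
        assert quartet.branch_duration(ab) == pytest.approx(10.0)
        assert quartet.child_age(ab) == pytest.approx(10.0)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            StatusTree.from_newick("((A:1,B:5):1,C:2);")

    def test_mrca_branch(self, quartet):
        assert quartet.mrca_branch(["A", "B"]) == frozenset("AB")
        with pytest.raises(ValueError, match="root"):
            quartet.mrca_branch(["A", "B", "C", "D"])


class TestRecordIdentity:
    def test_exact_match(self):
        assert records_match(_mut("a"), _mut("b"))

    def test_containment_deletion(self):
        a = _mut("a", kind="deletion", position=10, length=2)
        b = _mut("b", kind="deletion", position=9, length=5)
        assert records_match(a, b)

    def test_containment_insertion_extension(self):
        # a shared 2-base insertion extended to 5 bases in one lineage
        a = _mut("a", kind="insertion", position=96, length=2, alt="GG")
        b = _mut("b", kind="insertion", position=96, length=5, alt="GGCAG")
        assert records_match(a, b)

    def test_different_positions_do_not_match(self):
        assert not records_match(_mut("a", position=10), _mut("b", position=11))


class TestInferLossEvents:
    def test_galliform_eight_events(self, galliform):
        events = infer_loss_events(
            galliform.tree, galliform.catalogs, reference=galliform.reference
        )
        assert len(events) == 8
        species_by_event = {frozenset(e.species) for e in events}
        assert frozenset({"Pavo_cristatus", "Pavo_muticus"}) in species_by_event
        grouse = frozenset(
            {"Tympanuchus_cupido", "Centrocercus_minimus", "Lagopus_muta", "Lyrurus_tetrix"}
        )
        assert grouse in species_by_event

    def test_rodent_four_events(self, rodent):
        events = infer_loss_events(
            rodent.tree, rodent.catalogs, reference=rodent.reference
        )
        assert len(events) == 4
        sciuridae = frozenset(
            {
                "Urocitellus_parryii",
                "Spermophilus_dauricus",
                "Ictidomys_tridecemlineatus",
                "Marmota_marmota",
            }
        )
        assert sciuridae in {frozenset(e.species) for e in events}

    def test_singleton_event_on_terminal_branch(self, quartet):
        events = infer_loss_events(quartet, {"A": [_mut("A")]})
        assert len(events) == 1
        assert events[0].branch == frozenset({"A"})

    def test_order_invariance(self, galliform):
        base = infer_loss_events(
            galliform.tree, galliform.catalogs, reference=galliform.reference
        )
        shuffled = dict(reversed(list(galliform.catalogs.items())))
        other = infer_loss_events(
            galliform.tree, shuffled, reference=galliform.reference
        )
        assert {frozenset(e.species) for e in base} == {
            frozenset(e.species) for e in other
        }
        assert len(base) == len(other)

    def test_homoplastic_sharing_flagged_not_split(self):
        # A and C share a mutation but are not a clade; the event sits on the
        # stem of their MRCA and is flagged, never silently split
        tree = StatusTree.from_newick("(((A:5,B:5):5,(C:8,D:8):2):10,E:20);")
        catalogs = {"A": [_mut("A")], "C": [_mut("C")]}
        events = infer_loss_events(tree, catalogs)
        assert len(events) == 1
        assert events[0].homoplastic
        assert events[0].species == frozenset({"A", "C"})
        assert events[0].branch == frozenset({"A", "B", "C", "D"})

    def test_private_mutations_attach_to_shared_event(self, quartet):
        catalogs = {
            "A": [_mut("A"), _mut("A", position=50)],
            "B": [_mut("B")],
        }
        (event,) = infer_loss_events(quartet, catalogs)
        assert len(event.shared_mutations) == 1
        assert [m.position for m in event.private_mutations] == [50]

    def test_unknown_species_rejected(self, quartet):
        with pytest.raises(ValueError, match="not on the tree"):
            infer_loss_events(quartet, {"Z": [_mut("Z")]})

    def test_simulated_loss_counts_recovered(self, galliform):
        """k losses on non-nested branches with event-specific shared
        mutations always come back as exactly k events."""
        tree = galliform.tree
        terminals = sorted(
            (b for b in tree.branches() if len(b) == 1), key=sorted
        )
        rng = np.random.default_rng(99)
        for _ in range(100):
            k = int(rng.integers(1, 6))
            chosen = rng.choice(len(terminals), size=k, replace=False)
            catalogs = {}
            for i, idx in enumerate(chosen):
                (sp,) = terminals[idx]
                catalogs[sp] = [_mut(sp, exon=1, position=10 + 20 * i)]
            events = infer_loss_events(tree, catalogs)
            assert len(events) == k


class TestLabelBranches:
    def test_zero_events_all_functional(self, quartet):
        labeled = label_branches(quartet, [])
        assert set(labeled.labels.values()) == {FUNCTIONAL}

    def test_singleton_event_one_mixed_no_pseudogenic(self, quartet):
        event = LossEvent("e1", frozenset({"A"}), frozenset({"A"}))
        labeled = label_branches(quartet, [event])
        assert labeled.labels[frozenset({"A"})] == MIXED
        assert sum(1 for v in labeled.labels.values() if v == PSEUDOGENIC) == 0

    def test_clade_event_descendants_pseudogenic(self, galliform):
        events = infer_loss_events(
            galliform.tree, galliform.catalogs, reference=galliform.reference
        )
        labeled = label_branches(galliform.tree, events)
        assert sum(1 for v in labeled.labels.values() if v == MIXED) == 8
        grouse_stem = labeled.mrca_branch(
            ["Tympanuchus_cupido", "Centrocercus_minimus", "Lagopus_muta", "Lyrurus_tetrix"]
        )
        assert labeled.labels[grouse_stem] == MIXED
        for desc in labeled.descendant_branches(grouse_stem):
            assert labeled.labels[desc] == PSEUDOGENIC
        # label conservation: every branch exactly one label
        assert set(labeled.labels) == set(galliform.tree.labels)

    def test_labeling_idempotent(self, quartet):
        event = LossEvent("e1", frozenset({"A", "B"}), frozenset({"A", "B"}))
        once = label_branches(quartet, [event])
        twice = label_branches(once, [event])
        assert once.labels == twice.labels

    def test_nested_events_rejected(self, quartet):
        events = [
            LossEvent("e1", frozenset({"A", "B"}), frozenset({"A", "B"})),
            LossEvent("e2", frozenset({"A"}), frozenset({"A"})),
        ]
        with pytest.raises(ValueError, match="nested"):
            label_branches(quartet, events)


BIRD_ORDER = (
    "BLVRA VOPP1 LANCL2 EGFR SEC61G COA1 STK17A HECW1 MRPL32 PSMA2 C7orf25".split()
)


class TestDetectBreakpoints:
    def test_conserved_bird_order(self):
        ref = GeneOrder("reference", tuple(BIRD_ORDER))
        query = GeneOrder("bird", tuple(BIRD_ORDER))
        report = detect_breakpoints(ref, query)
        assert report.broken_adjacencies == []
        assert report.missing_genes == []
        assert report.moved_segments == []

    def test_excised_block_on_other_chromosome(self):
        ref = GeneOrder("reference", tuple("ABCDEFG"))
        query = GeneOrder(
            "query",
            tuple("ABEFG") + tuple("CD"),
            chromosomes=("chr1",) * 5 + ("chr2",) * 2,
        )
        report = detect_breakpoints(ref, query)
        assert sorted(report.broken_adjacencies) == [("B", "C"), ("D", "E")]
        assert report.moved_segments == [(("C", "D"), "chr2")]

    def test_reversed_adjacency_is_retained(self):
        ref = GeneOrder("reference", ("A", "B", "C"))
        query = GeneOrder("query", ("B", "A", "C"))
        report = detect_breakpoints(ref, query)
        assert ("A", "B") not in report.broken_adjacencies

    def test_length_one_reference(self):
        report = detect_breakpoints(GeneOrder("r", ("A",)), GeneOrder("q", ("A",)))
        assert report.broken_adjacencies == []

    def test_missing_gene_breaks_adjacency(self):
        ref = GeneOrder("reference", ("A", "B", "C"))
        query = GeneOrder("query", ("A", "C"))
        report = detect_breakpoints(ref, query)
        assert report.missing_genes == ["B"]
        assert len(report.broken_adjacencies) == 2

    def test_duplicate_symbol_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneOrder("query", ("A", "B", "A"))

    def test_self_comparison_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            genes = tuple(f"g{i}" for i in range(int(rng.integers(1, 12))))
            order = GeneOrder("x", genes)
            assert detect_breakpoints(order, order).broken_adjacencies == []
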