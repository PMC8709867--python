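"""Exon models, mutation application and the disruption scanner."""

import numpy as np
import pytest

from genedecay.gene_models import (
    GeneModel,
    GeneStatus,
    MutationRecord,
    DisruptionReport,
    apply_mutations,
    classify_status,
    compute_phases,
    resolve_record,
    scan_disruptions,
    splice,
    translate,
)
from tests.conftest import canonical_records


class TestSpliceAndTranslate:
    def test_single_exon_identity(self):
        g = GeneModel.from_sequences("s", "g", ["ATGTAA"])
        assert splice(g) == "ATGTAA"

    def test_concatenation(self):
        g = GeneModel.from_sequences("s", "g", ["ATGAA", "ATAA"])
        assert splice(g) == "ATGAAATAA"

    def test_length_conservation_on_fixture(self, rodent):
        assert len(splice(rodent.reference)) == sum(
            len(e) for e in rodent.reference.exons
        )

    @pytest.mark.parametrize(
        "cds,offset,protein,stops",
        [
            ("ATGTAA", 0, "M*", [(4, "TAA")]),
            ("GAA", 0, "E", []),
            ("TAA", 0, "*", [(1, "TAA")]),
            # frameshifted read of ATGAAATAG: TGA AAT AG -> "*N"
            ("ATGAAATAG", 1, "*N", [(1, "TGA")]),
        ],
    )
    def test_translate_examples(self, cds, offset, protein, stops):
        got_protein, got_stops = translate(cds, offset)
        assert got_protein == protein
        assert got_stops == stops

    def test_translate_ignores_trailing_bases(self):
        assert translate("ATGAA")[0] == "M"

    def test_translate_rejects_non_acgt(self):
        with pytest.raises(ValueError, match="base 5"):
            translate("ATGANA")

    def test_empty_exon_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneModel.from_sequences("s", "g", ["ATG", ""])


class TestPhases:
    def test_phase_recurrence(self):
        # phase(k+1) = (3 - cumlen % 3) % 3
        assert compute_phases([100, 105, 90, 104]) == [0, 2, 2, 2]
        assert compute_phases([120, 120, 81, 105]) == [0, 0, 0, 0]

    def test_inconsistent_phase_rejected(self):
        from genedecay.gene_models import ExonModel

        with pytest.raises(ValueError, match="phase"):
            GeneModel(
                species="s",
                gene="g",
                exons=(
                    ExonModel(1, "ATGA", 0),
                    ExonModel(2, "AAA", 0),  # should be phase 2
                ),
            )


class TestApplyMutations:
    def test_chicken_style_stop_gain(self, galliform):
        # G -> T at exon-2 base 69 turns the GAA codon (bases 69-71, exon-2
        # phase 2 so codons begin at local base 3) into TAA
        ref = galliform.reference
        assert ref.exons[1].sequence[68:71] == "GAA"
        obs = apply_mutations(ref, galliform.catalogs["Gallus_gallus"])
        assert obs.exons[1].sequence[68:71] == "TAA"

    def test_quail_style_two_substitutions(self, galliform):
        # AAC at exon-2 bases 48-50 becomes TAA via substitutions at 48 and 50
        ref = galliform.reference
        assert ref.exons[1].sequence[47:50] == "AAC"
        obs = apply_mutations(ref, galliform.catalogs["Coturnix_japonica"])
        assert obs.exons[1].sequence[47:50] == "TAA"

    def test_empty_list_is_identity(self, tiny_reference):
        assert apply_mutations(tiny_reference, []) == tiny_reference

    def test_indels_change_length_and_phases(self, tiny_reference):
        out = apply_mutations(
            tiny_reference,
            [MutationRecord(species="s", exon=1, kind="deletion", position=4)],
        )
        assert len(out.exons[0]) == 8
        assert out.exons[1].phase == 1

    def test_insertion_position_zero(self, tiny_reference):
        out = apply_mutations(
            tiny_reference,
            [MutationRecord(species="s", exon=2, kind="insertion", position=0,
                            length=2, alt="GG")],
        )
        assert out.exons[1].sequence.startswith("GG")

    def test_out_of_range_rejected(self, tiny_reference):
        with pytest.raises(ValueError, match="outside"):
            apply_mutations(
                tiny_reference,
                [MutationRecord(species="s", exon=1, kind="deletion", position=99)],
            )

    def test_overlapping_edits_rejected(self, tiny_reference):
        muts = [
            MutationRecord(species="s", exon=1, kind="deletion", position=4, length=3),
            MutationRecord(species="s", exon=1, kind="substitution", position=5, alt="T"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            apply_mutations(tiny_reference, muts)

    def test_noop_substitution_warns(self, tiny_reference):
        mut = MutationRecord(species="s", exon=1, kind="substitution", position=1, alt="A")
        with pytest.warns(UserWarning, match="no-op"):
            apply_mutations(tiny_reference, [mut])

    def test_codon_anchor_resolution(self, rodent):
        # phase-0 exon: codon n starts at base 3n-2
        rec = MutationRecord(
            species="s", exon=2, kind="deletion", position=13, anchor_unit="codon"
        )
        assert resolve_record(rec, rodent.reference).position == 37
        ins = MutationRecord(
            species="s", exon=3, kind="insertion", position=11, length=5,
            alt="CAGCA", anchor_unit="codon",
        )
        # insertion between codons 11 and 12 = after base 33
        assert resolve_record(ins, rodent.reference).position == 33


class TestScanDisruptions:
    def test_identical_gene_is_intact(self, rodent):
        report = scan_disruptions(rodent.reference, rodent.reference)
        assert report.status == GeneStatus.INTACT
        assert report.mutations_detected == []
        assert report.premature_stops == []

    def test_in_frame_deletion_stays_intact(self, rodent):
        ref = rodent.reference
        mut = MutationRecord(species="s", exon=2, kind="deletion", position=40, length=3)
        obs = apply_mutations(ref, [mut])
        report = scan_disruptions(ref, obs)
        kinds = [(m.kind, m.length) for m in report.mutations_detected]
        assert kinds == [("deletion", 3)]
        assert report.terminal_frame_offset == -3
        assert report.status == GeneStatus.INTACT

    def test_missing_gene(self, rodent):
        report = scan_disruptions(rodent.reference, None)
        assert report.status == GeneStatus.MISSING

    def test_unalignable_exon_flagged(self, rodent):
        ref = rodent.reference
        seqs = [e.sequence for e in ref.exons]
        rng = np.random.default_rng(0)
        seqs[2] = "".join(rng.choice(list("ACGT"), size=60))
        obs = GeneModel.from_sequences("weird", "focal", seqs)
        report = scan_disruptions(ref, obs)
        assert 3 in report.unalignable_exons
        assert all(m.exon != 3 for m in report.mutations_detected)

    def test_scan_requires_intact_reference(self, rodent):
        broken = apply_mutations(
            rodent.reference,
            [MutationRecord(species="s", exon=1, kind="deletion", position=10)],
        )
        with pytest.raises(ValueError, match="intact"):
            scan_disruptions(broken, rodent.reference)


def _random_catalog(rng, reference, max_edits=5):
    """Well-separated random edits of the kind pseudogene decay produces.

    Substitution runs are fully mismatched and inserted strings mismatch the
    flanking reference windows, so the minimal-cost alignment is the edit
    itself (an inserted string that happens to copy its context is genuinely
    unrecoverable by any aligner).
    """
    records = []
    for exon in reference.exons:
        n_edits = rng.integers(0, max_edits // 2 + 1)
        positions = []
        for _ in range(n_edits):
            length = int(rng.integers(1, 5))
            pos = int(rng.integers(4, len(exon) - length - 4))
            if any(abs(pos - p) < 14 for p in positions):
                continue
            positions.append(pos)
            kind = rng.choice(["substitution", "insertion", "deletion"])
            if kind == "substitution":
                ref_bases = exon.sequence[pos - 1 : pos - 1 + length]
                alt = "".join(
                    rng.choice([b for b in "ACGT" if b != r]) for r in ref_bases
                )
            elif kind == "insertion":
                alt = ""
                for i in range(length):
                    avoid = {exon.sequence[pos + i]}  # right flank
                    if pos - length + i >= 0:
                        avoid.add(exon.sequence[pos - length + i])  # left flank
                    alt += rng.choice([b for b in "ACGT" if b not in avoid])
            else:
                alt = ""
            records.append(
                MutationRecord(species="x", exon=exon.index, kind=kind,
                               position=pos, length=length, alt=alt)
            )
    return records


class TestScannerProperties:
    def test_round_trip_recovers_catalogs(self, rodent):
        """scan(ref, apply(ref, M)) == M for random well-separated catalogs."""
        ref = rodent.reference
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(300):
            catalog = _random_catalog(rng, ref)
            if not catalog:
                continue
            obs = apply_mutations(ref, catalog)
            report = scan_disruptions(ref, obs)
            assert canonical_records(report.mutations_detected, ref) == \
                canonical_records(catalog, ref)
            # frame conservation: indel sum == reported terminal offset
            net = sum(m.frame_shift() for m in catalog)
            assert report.terminal_frame_offset == net
            checked += 1
        assert checked > 200

    def test_premature_stops_match_brute_force_translation(self, galliform):
        """Stop calls equal a direct scan of the spliced mutant sequence."""
        for species in galliform.expected_disrupted:
            obs = galliform.observed_gene(species)
            report = scan_disruptions(galliform.reference, obs)
            spliced = splice(obs)
            expected = []
            for start in range(0, len(spliced) - len(spliced) % 3, 3):
                codon = spliced[start : start + 3]
                if codon in {"TAA", "TAG", "TGA"}:
                    if start == len(spliced) - 3 and len(spliced) % 3 == 0:
                        continue
                    expected.append(codon)
            assert [c for _, _, c in report.premature_stops] == expected

    def test_phase_bookkeeping_after_edits(self, rodent):
        ref = rodent.reference
        rng = np.random.default_rng(7)
        for _ in range(50):
            catalog = _random_catalog(rng, ref)
            obs = apply_mutations(ref, catalog)
            assert compute_phases([len(e) for e in obs.exons]) == [
                e.phase for e in obs.exons
            ]


class TestClassifyStatus:
    def _report(self, **kw):
        base = dict(
            species="s",
            mutations_detected=[],
            premature_stops=[],
            net_frame_offset_per_exon=[0],
            start_codon_intact=True,
        )
        base.update(kw)
        return DisruptionReport(**base)

    @pytest.mark.parametrize(
        "kw,expected",
        [
            ({}, GeneStatus.INTACT),
            ({"premature_stops": [(1, 4, "TAA")]}, GeneStatus.DISRUPTED),
            ({"net_frame_offset_per_exon": [2]}, GeneStatus.DISRUPTED),
            ({"net_frame_offset_per_exon": [0, -3]}, GeneStatus.INTACT),
            ({"start_codon_intact": False}, GeneStatus.DISRUPTED),
            # stop-loss alone does not disrupt
            ({"stop_loss": True}, GeneStatus.INTACT),
        ],
    )
    def test_rule_table(self, kw, expected):
        assert classify_status(self._report(**kw)) == expected
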