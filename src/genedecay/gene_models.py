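"""Exon-structured gene models and reading-frame disruption scanning.

A gene is represented as an ordered list of coding exons.  Each exon carries a
*phase*: the number of 5'-terminal bases that complete a codon begun in the
previous exon (0, 1 or 2).  Mutation evidence is recorded in the coordinate
idiom of comparative pseudogene studies — exon-local, 1-based positions on the
coding strand, with insertions anchored "after base p" (p = 0 meaning before
the first base) and codon-anchored records resolved to base coordinates
through the exon phase.

The scanner compares an observed gene against an intact reference exon by
exon with a global affine-gap alignment, reconstructs the mutation catalog,
tracks the cumulative reading-frame offset across the spliced sequence, and
calls premature stop codons by translating the observed spliced sequence.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TO_AA = dict(standard_dna_table.forward_table)


class GeneStatus(str, enum.Enum):
    """Functional status of an observed gene copy."""

    INTACT = "intact"
    DISRUPTED = "disrupted"
    MISSING = "missing"


@dataclass(frozen=True)
class ExonModel:
    """One coding exon.

    Parameters
    ----------
    index : int
        1-based exon number within the gene.
    sequence : str
        Coding-strand DNA over {A, C, G, T}.
    phase : int
        Number of 5'-terminal bases completing a codon begun in the previous
        exon; exon 1 has phase 0.
    """

    index: int
    sequence: str
    phase: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"exon {self.index}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"exon {self.index}: non-ACGT characters {sorted(bad)}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"exon {self.index}: phase must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


def compute_phases(lengths: Sequence[int]) -> list[int]:
    """Exon phases implied by exon lengths: phase(k+1) = (3 - cumlen_k % 3) % 3."""
    phases = [0]
    cum = 0
    for n in lengths[:-1]:
        cum += n
        phases.append((3 - cum % 3) % 3)
    return phases


@dataclass(frozen=True)
class GeneModel:
    """A species-tagged, exon-structured coding gene."""

    species: str
    gene: str
    exons: tuple[ExonModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        expected = compute_phases([len(e) for e in self.exons])
        for exon, phase in zip(self.exons, expected):
            if exon.phase != phase:
                raise ValueError(
                    f"{self.species}/{self.gene} exon {exon.index}: phase "
                    f"{exon.phase} inconsistent with cumulative length (expect {phase})"
                )

    @classmethod
    def from_sequences(cls, species: str, gene: str, sequences: Sequence[str]) -> "GeneModel":
        phases = compute_phases([len(s) for s in sequences])
        exons = tuple(
            ExonModel(index=i + 1, sequence=s, phase=p)
            for i, (s, p) in enumerate(zip(sequences, phases))
        )
        return cls(species=species, gene=gene, exons=exons)

    def is_intact_reference(self) -> bool:
        """Intact reference: spliced length % 3 == 0, starts ATG, single terminal stop."""
        cds = splice(self)
        if len(cds) % 3 or not cds.startswith("ATG"):
            return False
        _, stops = translate(cds)
        return len(stops) == 1 and stops[0][0] == len(cds) - 2


@dataclass(frozen=True)
class MutationRecord:
    """One substitution, insertion or deletion in exon-local coordinates.

    ``position`` is 1-based within the exon.  For insertions it names the base
    *after which* the new bases sit (0 = before the first base).  Records may
    be anchored on bases or on codons; codon anchors are resolved to base
    coordinates through the exon phase before application (substitutions and
    deletions to the codon's first base, insertions to the gap after the
    codon's last base).
    """

    species: str
    exon: int
    kind: str  # substitution | insertion | deletion
    position: int
    length: int = 1
    alt: str = ""
    anchor_unit: str = "base"  # base | codon

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.anchor_unit not in ("base", "codon"):
            raise ValueError(f"unknown anchor unit {self.anchor_unit!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind in ("substitution", "insertion"):
            if len(self.alt) != self.length:
                raise ValueError(f"{self.kind} requires |alt| == length")
            if set(self.alt) - _ALPHABET:
                raise ValueError("alt must be ACGT")
        elif self.alt:
            raise ValueError("deletion must have empty alt")

    def frame_shift(self) -> int:
        if self.kind == "insertion":
            return self.length
        if self.kind == "deletion":
            return -self.length
        return 0


def resolve_record(record: MutationRecord, gene: GeneModel) -> MutationRecord:
    """Resolve a codon-anchored record to base coordinates on ``gene``.

    Codon *n* of an exon with phase *p* occupies local bases
    ``p + 3(n-1) + 1 .. p + 3n``.  Substitutions and deletions resolve to the
    codon's first base; an insertion "at codon position n" resolves to the gap
    after codon *n*'s last base (i.e. between codons n and n+1).
    """
    if record.anchor_unit == "base":
        return record
    exon = _get_exon(gene, record.exon)
    p = exon.phase
    if record.kind == "insertion":
        base = p + 3 * record.position
    else:
        base = p + 3 * (record.position - 1) + 1
    return replace(record, position=base, anchor_unit="base")


def _get_exon(gene: GeneModel, index: int) -> ExonModel:
    for exon in gene.exons:
        if exon.index == index:
            return exon
    raise ValueError(f"{gene.species}/{gene.gene}: no exon {index}")


@dataclass
class DisruptionReport:
    """Result of scanning an observed gene against an intact reference."""

    species: str
    mutations_detected: list[MutationRecord]
    premature_stops: list[tuple[int, int, str]]  # (exon, exon-local codon start base, codon)
    net_frame_offset_per_exon: list[int]  # cumulative raw indel sums per exon
    start_codon_intact: bool
    stop_loss: bool = False
    missing_exons: list[int] = field(default_factory=list)
    unalignable_exons: list[int] = field(default_factory=list)
    status: GeneStatus = GeneStatus.INTACT

    @property
    def terminal_frame_offset(self) -> int:
        return self.net_frame_offset_per_exon[-1] if self.net_frame_offset_per_exon else 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def splice(gene: GeneModel) -> str:
    """Concatenate exon sequences in order to the spliced CDS."""
    return "".join(exon.sequence for exon in gene.exons)


def translate(cds: str, frame_offset: int = 0) -> tuple[str, list[tuple[int, str]]]:
    """Translate ``cds`` (after skipping ``frame_offset`` bases) codon by codon.

    Returns the amino-acid string (stops as ``*``; translation continues
    through internal stops) and the list of stop codons as
    ``(1-based base coordinate of the codon start in the shifted frame,
    codon string)``.  Trailing 1-2 bases are ignored.
    """
    seq = cds[frame_offset:]
    protein = []
    stops: list[tuple[int, str]] = []
    for start in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[start : start + 3]
        bad = set(codon) - _ALPHABET
        if bad:
            offending = start + min(codon.index(b) for b in bad) + 1
            raise ValueError(f"non-ACGT character at base {offending} of the frame")
        if codon in STOP_CODONS:
            protein.append("*")
            stops.append((start + 1, codon))
        else:
            protein.append(_CODON_TO_AA[codon])
    return "".join(protein), stops


def apply_mutations(gene: GeneModel, muts: Iterable[MutationRecord]) -> GeneModel:
    """Return a copy of ``gene`` with all mutation records applied.

    Records are resolved to base coordinates, grouped by exon and applied in
    descending position order so that coordinates remain valid.  Overlapping
    edits raise; a substitution identical to the reference emits a no-op
    warning.  Downstream exon phases are recomputed from the edited lengths.
    """
    by_exon: dict[int, list[MutationRecord]] = {}
    for m in muts:
        by_exon.setdefault(m.exon, []).append(resolve_record(m, gene))

    new_seqs: list[str] = []
    for exon in gene.exons:
        seq = exon.sequence
        records = by_exon.pop(exon.index, [])
        _check_overlaps(records, exon)
        for m in sorted(records, key=lambda r: r.position, reverse=True):
            seq = _apply_one(seq, m, exon)
        if not seq:
            raise ValueError(f"exon {exon.index} empty after edits")
        new_seqs.append(seq)
    if by_exon:
        raise ValueError(f"mutations reference unknown exons {sorted(by_exon)}")
    return GeneModel.from_sequences(gene.species, gene.gene, new_seqs)


def _interval(m: MutationRecord) -> tuple[float, float]:
    # insertions occupy the zero-width gap after `position`
    if m.kind == "insertion":
        return (m.position + 0.25, m.position + 0.75)
    return (float(m.position), float(m.position + m.length - 1))


def _check_overlaps(records: list[MutationRecord], exon: ExonModel) -> None:
    spans = sorted((_interval(m), m) for m in records)
    for (a, ma), (b, mb) in zip(spans, spans[1:]):
        if b[0] <= a[1]:
            raise ValueError(
                f"overlapping edits in exon {exon.index}: "
                f"{ma.kind}@{ma.position} and {mb.kind}@{mb.position}"
            )


def _apply_one(seq: str, m: MutationRecord, exon: ExonModel) -> str:
    n = len(seq)
    if m.kind == "insertion":
        if not 0 <= m.position <= n:
            raise ValueError(f"insertion position {m.position} outside exon {exon.index}")
        return seq[: m.position] + m.alt + seq[m.position :]
    if not 1 <= m.position <= n - m.length + 1:
        raise ValueError(
            f"{m.kind} at {m.position} (length {m.length}) outside exon {exon.index}"
        )
    i = m.position - 1
    if m.kind == "substitution":
        if seq[i : i + m.length] == m.alt:
            warnings.warn(
                f"no-op substitution at exon {exon.index} base {m.position}",
                stacklevel=3,
            )
        return seq[:i] + m.alt + seq[i + m.length :]
    return seq[:i] + seq[i + m.length :]  # deletion


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # a gap of length L costs 4 + L
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def left_normalize(record: MutationRecord, ref_seq: str) -> MutationRecord:
    """Shift an indel to its leftmost equivalent placement on ``ref_seq``.

    A deletion of ``ref[p-1:p-1+L]`` can slide left one base whenever the base
    entering the window equals the base leaving it; likewise an insertion can
    slide left while the inserted string rotated by the preceding reference
    base yields the same edited sequence.  Substitutions are returned as-is.
    """
    if record.kind == "substitution":
        return record
    if record.kind == "deletion":
        p, L = record.position, record.length
        while p > 1 and ref_seq[p - 2] == ref_seq[p - 2 + L]:
            p -= 1
        return replace(record, position=p)
    # insertion after base p with string alt; sliding left past ref base b is
    # equivalent when alt ends with b: insert(p-1, b + alt[:-1])
    p, alt = record.position, record.alt
    while p > 0 and alt[-1] == ref_seq[p - 1]:
        alt = ref_seq[p - 1] + alt[:-1]
        p -= 1
    return replace(record, position=p, alt=alt)


def _mutations_from_alignment(
    species: str, exon_index: int, ref: str, obs: str
) -> list[MutationRecord]:
    """Derive mutation records from the best global alignment of obs onto ref."""
    alignment = _ALIGNER.align(ref, obs)[0]
    ref_blocks, obs_blocks = alignment.aligned
    records: list[MutationRecord] = []

    def add_sub(ref_pos0: int, ref_bases: str, alt: str) -> None:
        records.append(
            MutationRecord(
                species=species,
                exon=exon_index,
                kind="substitution",
                position=int(ref_pos0) + 1,
                length=len(alt),
                alt=alt,
            )
        )

    prev_r_end = 0
    prev_q_end = 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, obs_blocks):
        if r0 > prev_r_end:  # unmatched ref = deletion
            records.append(
                MutationRecord(
                    species=species,
                    exon=exon_index,
                    kind="deletion",
                    position=int(prev_r_end) + 1,
                    length=int(r0 - prev_r_end),
                )
            )
        if q0 > prev_q_end:  # unmatched obs = insertion after last aligned ref base
            records.append(
                MutationRecord(
                    species=species,
                    exon=exon_index,
                    kind="insertion",
                    position=int(r0 if r0 > prev_r_end else prev_r_end),
                    length=int(q0 - prev_q_end),
                    alt=obs[prev_q_end:q0],
                )
            )
        # mismatch runs inside the matched block
        run_start = None
        for k in range(r1 - r0):
            if ref[r0 + k] != obs[q0 + k]:
                if run_start is None:
                    run_start = k
            elif run_start is not None:
                add_sub(r0 + run_start, ref[r0 + run_start : r0 + k], obs[q0 + run_start : q0 + k])
                run_start = None
        if run_start is not None:
            add_sub(r0 + run_start, ref[r0 + run_start : r1], obs[q0 + run_start : q1])
        prev_r_end, prev_q_end = r1, q1
    if len(ref) > prev_r_end:
        records.append(
            MutationRecord(
                species=species,
                exon=exon_index,
                kind="deletion",
                position=prev_r_end + 1,
                length=len(ref) - prev_r_end,
            )
        )
    if len(obs) > prev_q_end:
        records.append(
            MutationRecord(
                species=species,
                exon=exon_index,
                kind="insertion",
                position=len(ref),
                length=len(obs) - prev_q_end,
                alt=obs[prev_q_end:],
            )
        )
    records = [left_normalize(m, ref) for m in records]
    return sorted(records, key=lambda m: (m.position, m.kind))


def _alignment_identity(ref: str, obs: str) -> float:
    alignment = _ALIGNER.align(ref, obs)[0]
    ref_blocks, obs_blocks = alignment.aligned
    matches = sum(
        1
        for (r0, r1), (q0, q1) in zip(ref_blocks, obs_blocks)
        for k in range(r1 - r0)
        if ref[r0 + k] == obs[q0 + k]
    )
    return matches / max(len(ref), 1)


def scan_disruptions(ref: GeneModel, obs: GeneModel | None) -> DisruptionReport:
    """Scan an observed gene against an intact reference for ORF disruptions.

    Per exon, a global affine-gap alignment of the observed sequence onto the
    reference yields mutation records (indels left-normalized, contiguous
    mismatch runs merged).  The cumulative raw indel sum is tracked across the
    spliced sequence, and premature stops are called by translating the
    observed spliced sequence — frameshifts therefore propagate downstream
    exactly as they do in the genome.  Exons aligning at < 50% identity are
    flagged unalignable and excluded from mutation calling.
    """
    if not ref.is_intact_reference():
        raise ValueError("reference gene is not an intact ORF")
    if obs is None or not obs.exons:
        return DisruptionReport(
            species=getattr(obs, "species", "?"),
            mutations_detected=[],
            premature_stops=[],
            net_frame_offset_per_exon=[],
            start_codon_intact=False,
            status=GeneStatus.MISSING,
        )

    obs_by_index = {e.index: e for e in obs.exons}
    mutations: list[MutationRecord] = []
    missing: list[int] = []
    unalignable: list[int] = []
    offsets: list[int] = []
    observed_segments: list[tuple[int, str]] = []  # (exon index, observed sequence)
    cumulative = 0
    for r_exon in ref.exons:
        o_exon = obs_by_index.get(r_exon.index)
        if o_exon is None:
            missing.append(r_exon.index)
            offsets.append(cumulative)
            continue
        if _alignment_identity(r_exon.sequence, o_exon.sequence) < 0.5:
            unalignable.append(r_exon.index)
            offsets.append(cumulative)
            continue
        found = _mutations_from_alignment(
            obs.species, r_exon.index, r_exon.sequence, o_exon.sequence
        )
        mutations.extend(found)
        cumulative += sum(m.frame_shift() for m in found)
        offsets.append(cumulative)
        observed_segments.append((r_exon.index, o_exon.sequence))

    spliced_obs = "".join(seq for _, seq in observed_segments)
    start_ok = spliced_obs.startswith("ATG")

    protein, stops = translate(spliced_obs) if len(spliced_obs) >= 3 else ("", [])
    n_codons = len(spliced_obs) // 3
    premature: list[tuple[int, int, str]] = []
    stop_loss = True
    for base, codon in stops:
        codon_index = (base - 1) // 3 + 1
        if codon_index == n_codons and len(spliced_obs) % 3 == 0:
            stop_loss = False  # terminal codon is a stop
        else:
            premature.append((*_spliced_to_exon_local(base, observed_segments), codon))

    report = DisruptionReport(
        species=obs.species,
        mutations_detected=mutations,
        premature_stops=premature,
        net_frame_offset_per_exon=offsets,
        start_codon_intact=start_ok,
        stop_loss=stop_loss,
        missing_exons=missing,
        unalignable_exons=unalignable,
    )
    report.status = classify_status(report)
    return report


def _spliced_to_exon_local(
    base: int, segments: list[tuple[int, str]]
) -> tuple[int, int]:
    """Map a 1-based spliced coordinate to (exon index, exon-local base)."""
    offset = 0
    for exon_index, seq in segments:
        if base <= offset + len(seq):
            return exon_index, base - offset
        offset += len(seq)
    return segments[-1][0], base - offset + len(segments[-1][1])


def classify_status(report: DisruptionReport) -> GeneStatus:
    """Deterministic status rules.

    disrupted iff (>= 1 premature stop) or (terminal cumulative frame offset
    mod 3 != 0) or (start codon lost); missing iff no sequence was supplied.
    A destroyed terminal stop alone ("stop-loss") does not disrupt.
    """
    if not report.net_frame_offset_per_exon and not report.mutations_detected:
        if report.missing_exons or not report.start_codon_intact:
            return GeneStatus.MISSING
    if (
        report.premature_stops
        or report.terminal_frame_offset % 3 != 0
        or not report.start_codon_intact
    ):
        return GeneStatus.DISRUPTED
    return GeneStatus.INTACT
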