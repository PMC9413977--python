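"""V/J segment assignment, CDR3 extraction and QC against a germline library.

A simplified in-package annotator: best local alignment (match +5,
mismatch -4, gap open -8, gap extend -1) over the library's V segments,
then over the J segments in the region 3' of the V alignment, with CDR3
taken from the conserved germline anchor codons mapped through the
alignment.  Allele-level distinctions are out of scope; calls are gene
names as stored in the library.

Coordinates are 0-based half-open throughout.  The CDR3 reported here uses
the junction convention (both anchor codons included); ``cdr3_imgt`` views
strip them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

from .simulate import GermlineSegment

__all__ = [
    "ScoringParams",
    "SegmentAlignment",
    "Rearrangement",
    "assign_segments",
    "extract_cdr3",
    "qc_filter",
    "annotate_sequence",
]


@dataclass(frozen=True)
class ScoringParams:
    match: int = 5
    mismatch: int = -4
    gap_open: int = -8
    gap_extend: int = -1
    v_score_floor: int = 60
    j_score_floor: int = 25


@dataclass(frozen=True)
class SegmentAlignment:
    """A local alignment of one germline segment to a query sequence.

    ``blocks`` pairs aligned runs as ((seq_start, seq_end),
    (germline_start, germline_end)); gap columns fall between blocks and
    are excluded from identity.
    """

    segment: str
    score: float
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    matches: int
    aligned_length: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0

    @property
    def mutations(self) -> int:
        return self.aligned_length - self.matches

    @property
    def seq_start(self) -> int:
        return self.blocks[0][0][0]

    @property
    def seq_end(self) -> int:
        return self.blocks[-1][0][1]

    def germline_to_seq(self, gpos: int) -> int | None:
        """Map a germline position to a query position, None if unaligned."""
        for (ts, te), (qs, qe) in self.blocks:
            if qs <= gpos < qe:
                return ts + (gpos - qs)
        return None


@dataclass
class Rearrangement:
    """One annotated VDJ sequence."""

    sequence_id: str
    sequence: str
    v_call: str
    j_call: str
    v_identity: float
    v_mutations: int
    v_aligned_length: int
    v_alignment: SegmentAlignment
    j_alignment: SegmentAlignment
    cdr3_nt: str | None = None
    cdr3_start: int | None = None
    cdr3_end: int | None = None
    isotype: str | None = None
    duplicate_count: int = 1

    @property
    def cdr3_imgt(self) -> str | None:
        """CDR3 without the two anchor codons."""
        return None if self.cdr3_nt is None else self.cdr3_nt[3:-3]


def _aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _align_one(
    aligner: Align.PairwiseAligner, sequence: str, segment: GermlineSegment, offset: int = 0
) -> SegmentAlignment | None:
    alignments = aligner.align(sequence, segment.sequence)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    blocks = []
    matches = 0
    aligned = 0
    for (ts, te), (qs, qe) in zip(t_blocks.tolist(), q_blocks.tolist()):
        blocks.append(((ts + offset, te + offset), (qs, qe)))
        aligned += te - ts
        matches += sum(
            1 for a, b in zip(sequence[ts:te], segment.sequence[qs:qe]) if a == b
        )
    return SegmentAlignment(
        segment=segment.name,
        score=float(aln.score),
        blocks=tuple(blocks),
        matches=matches,
        aligned_length=aligned,
    )


def assign_segments(
    sequence: str,
    library: Sequence[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
) -> tuple[SegmentAlignment, SegmentAlignment] | None:
    """Assign the best V and J segments by local alignment.

    The highest-scoring V wins (ties broken lexicographically by name,
    enforced by iterating in name order and keeping strict improvements);
    the J is then sought 3' of the V alignment.  Returns None when the
    sequence is unassignable (V score below the floor, or no J).
    """
    vs = sorted((s for s in library if s.segment_class == "V"), key=lambda s: s.name)
    js = sorted((s for s in library if s.segment_class == "J"), key=lambda s: s.name)
    if not vs or not js:
        raise ValueError("library must contain V and J segments")
    aligner = _aligner(scoring)
    best_v: SegmentAlignment | None = None
    for v in vs:
        aln = _align_one(aligner, sequence, v)
        if aln is not None and (best_v is None or aln.score > best_v.score):
            best_v = aln
    if best_v is None or best_v.score < scoring.v_score_floor:
        return None
    tail_start = best_v.seq_end
    tail = sequence[tail_start:]
    best_j: SegmentAlignment | None = None
    if tail:
        for j in js:
            aln = _align_one(aligner, tail, j, offset=tail_start)
            if aln is not None and (best_j is None or aln.score > best_j.score):
                best_j = aln
    if best_j is None or best_j.score < scoring.j_score_floor:
        return None
    return best_v, best_j


def extract_cdr3(
    sequence: str,
    v_alignment: SegmentAlignment,
    j_alignment: SegmentAlignment,
    library_by_name: Mapping[str, GermlineSegment],
) -> tuple[str, int, int] | None:
    """Extract the CDR3 (junction convention: both anchor codons included).

    The germline V cysteine anchor and J Trp/Phe anchor are mapped through
    their alignments; absence (anchor outside the aligned region, or a span
    that is not a positive multiple of 3) is a value, not an error.
    """
    v_seg = library_by_name[v_alignment.segment]
    j_seg = library_by_name[j_alignment.segment]
    start = v_alignment.germline_to_seq(v_seg.anchor)
    anchor_end = v_alignment.germline_to_seq(v_seg.anchor + 2)
    j_anchor_last = j_alignment.germline_to_seq(j_seg.anchor + 2)
    j_anchor_first = j_alignment.germline_to_seq(j_seg.anchor)
    if None in (start, anchor_end, j_anchor_first, j_anchor_last):
        return None
    end = j_anchor_last + 1
    length = end - start
    if length <= 0 or length % 3 != 0:
        return None
    return sequence[start:end], start, end


def qc_filter(rearrangement: Rearrangement, min_v_len: int = 100) -> tuple[bool, str | None]:
    """Pass/fail a rearrangement: CDR3 must exist, V alignment not truncated.

    Returns ``(passed, reason)`` with reason ``no-cdr3`` or ``truncated``.
    """
    if rearrangement.cdr3_nt is None:
        return False, "no-cdr3"
    if rearrangement.v_aligned_length < min_v_len:
        return False, "truncated"
    return True, None


def annotate_sequence(
    sequence_id: str,
    sequence: str,
    library: Sequence[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
    isotype: str | None = None,
    duplicate_count: int = 1,
) -> Rearrangement | None:
    """Full annotation of one sequence; None when unassignable."""
    assigned = assign_segments(sequence, library, scoring)
    if assigned is None:
        return None
    v_aln, j_aln = assigned
    by_name = {s.name: s for s in library}
    rearr = Rearrangement(
        sequence_id=sequence_id,
        sequence=sequence,
        v_call=v_aln.segment,
        j_call=j_aln.segment,
        v_identity=v_aln.identity,
        v_mutations=v_aln.mutations,
        v_aligned_length=v_aln.aligned_length,
        v_alignment=v_aln,
        j_alignment=j_aln,
        isotype=isotype,
        duplicate_count=duplicate_count,
    )
    cdr3 = extract_cdr3(sequence, v_aln, j_aln, by_name)
    if cdr3 is not None:
        rearr.cdr3_nt, rearr.cdr3_start, rearr.cdr3_end = cdr3
    return rearr
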