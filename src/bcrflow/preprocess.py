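"""Read preprocessing: overlap merging, quality filter, primer tagging, dedup.

The chain mirrors a standard amplicon repertoire protocol: paired reads are
merged on their overlap, merged sequences below a mean Phred of 20 are
dropped, the constant-region primer is matched exactly at the 3' end of the
merged sense-strand sequence (tagging the isotype subclass and being
trimmed), and identical (sequence, isotype) records are collapsed with the
collapse multiplicity kept as ``duplicate_count``.

Orientation convention: read 2 is sequenced from the constant-region side,
so it begins with the primer as printed; merging reverse-complements read 2
and produces the sense strand, on which the primer appears reverse
complemented at the 3' end.  :func:`sense_primer_table` converts a printed
primer table to the sense-strand form used for tagging merged output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .simulate import revcomp

__all__ = [
    "ReadPair",
    "MergedRead",
    "ProcessedSequence",
    "TrimFailure",
    "merge_pair",
    "filter_quality",
    "trim_and_tag",
    "deduplicate",
    "sense_primer_table",
    "run_preprocess",
]


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        for q in (*self.qual1, *self.qual2):
            if not (0 <= q <= 93):
                raise ValueError(f"{self.id}: Phred score {q} outside [0, 93]")


@dataclass(frozen=True)
class MergedRead:
    id: str
    sequence: str
    quals: tuple[int, ...]
    overlap: int
    mismatches: int


@dataclass(frozen=True)
class ProcessedSequence:
    sequence: str
    isotype: str
    duplicate_count: int
    mean_q: float


@dataclass(frozen=True)
class TrimFailure:
    reason: str  # "no-primer" | "ambiguous-primer"


def merge_pair(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.25
) -> MergedRead | None:
    """Merge a read pair on the best suffix/prefix overlap, or return None.

    Read 2 is reverse-complemented, then every overlap length between
    ``min_overlap`` and the shorter mate is scored; among overlaps whose
    mismatch fraction is within ``max_mismatch_frac`` the one with the
    lowest fraction wins, longer overlap breaking ties.  Within the overlap
    the higher-quality base is kept and the merged quality is the max of
    the two.
    """
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"{pair.id}: empty mate")
    s1, q1 = pair.seq1, list(pair.qual1)
    s2 = revcomp(pair.seq2)
    q2 = list(pair.qual2)[::-1]
    best: tuple[float, int] | None = None  # (mismatch_frac, overlap)
    for o in range(min_overlap, min(len(s1), len(s2)) + 1):
        tail, head = s1[-o:], s2[:o]
        mism = sum(a != b for a, b in zip(tail, head))
        frac = mism / o
        if frac > max_mismatch_frac:
            continue
        if best is None or frac < best[0] or (frac == best[0] and o > best[1]):
            best = (frac, o)
    if best is None:
        return None
    frac, o = best
    merged_seq = list(s1[:-o])
    merged_q = q1[: len(s1) - o]
    mism = 0
    for i in range(o):
        a, b = s1[len(s1) - o + i], s2[i]
        qa, qb = q1[len(s1) - o + i], q2[i]
        if a != b:
            mism += 1
        merged_seq.append(a if qa >= qb else b)
        merged_q.append(max(qa, qb))
    merged_seq.extend(s2[o:])
    merged_q.extend(q2[o:])
    return MergedRead(
        id=pair.id,
        sequence="".join(merged_seq),
        quals=tuple(merged_q),
        overlap=o,
        mismatches=mism,
    )


def filter_quality(
    sequence: str, quals: Sequence[int], min_mean_q: float = 20.0
) -> bool:
    """Keep iff the arithmetic mean Phred score is >= ``min_mean_q``."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(quals) / len(quals) >= min_mean_q


def _validate_primer_table(primer_table: Mapping[str, str]) -> None:
    if not primer_table:
        raise ValueError("primer table is empty")
    items = list(primer_table.items())
    for i, (iso_a, a) in enumerate(items):
        for iso_b, b in items[i + 1 :]:
            if a.endswith(b) or b.endswith(a):
                raise ValueError(
                    f"primers for {iso_a} and {iso_b} are not suffix-free; "
                    "3'-end matching would be ambiguous"
                )


def trim_and_tag(
    sequence: str, primer_table: Mapping[str, str]
) -> tuple[str, str] | TrimFailure:
    """Exact-match one primer at the 3' end; trim it and tag the isotype.

    Returns ``(trimmed_sequence, isotype)`` or a :class:`TrimFailure` with
    reason ``no-primer`` or ``ambiguous-primer``.  Primer tables must be
    mutually suffix-free so at most one primer can match.
    """
    _validate_primer_table(primer_table)
    matches = [
        (iso, p) for iso, p in primer_table.items() if sequence.endswith(p)
    ]
    if not matches:
        return TrimFailure("no-primer")
    if len(matches) > 1:
        return TrimFailure("ambiguous-primer")
    iso, primer = matches[0]
    return sequence[: -len(primer)], iso


def sense_primer_table(primer_table: Mapping[str, str]) -> dict[str, str]:
    """Reverse-complement a printed primer table into sense-strand form."""
    return {iso: revcomp(p) for iso, p in primer_table.items()}


def deduplicate(
    records: Iterable[tuple[str, str, float]]
) -> list[ProcessedSequence]:
    """Collapse identical (sequence, isotype) records.

    Input records are ``(sequence, isotype, mean_q)``.  Output is ordered by
    descending duplicate_count, ties broken lexicographically by sequence
    then isotype; ``mean_q`` is the mean over collapsed records.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for seq, iso, mq in records:
        groups.setdefault((seq, iso), []).append(mq)
    out = [
        ProcessedSequence(
            sequence=seq,
            isotype=iso,
            duplicate_count=len(qs),
            mean_q=sum(qs) / len(qs),
        )
        for (seq, iso), qs in groups.items()
    ]
    out.sort(key=lambda r: (-r.duplicate_count, r.sequence, r.isotype))
    return out


def run_preprocess(
    pairs: Iterable[ReadPair],
    primer_table: Mapping[str, str],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    min_mean_q: float = 20.0,
    primers_are_printed: bool = True,
) -> tuple[list[ProcessedSequence], dict]:
    """Run the full merge -> quality -> primer -> dedup chain.

    ``primers_are_printed`` says the table holds primers as printed (read-2
    orientation); they are reverse-complemented for 3'-end matching on the
    merged sense strand.  Returns the unique tagged sequences and a count
    report with per-stage and per-discard-reason tallies.
    """
    table = sense_primer_table(primer_table) if primers_are_printed else dict(primer_table)
    report = {
        "input_pairs": 0,
        "merged": 0,
        "merge_failed": 0,
        "quality_passed": 0,
        "quality_failed": 0,
        "tagged": 0,
        "discard_no_primer": 0,
        "discard_ambiguous_primer": 0,
    }
    tagged: list[tuple[str, str, float]] = []
    for pair in pairs:
        report["input_pairs"] += 1
        merged = merge_pair(pair, min_overlap, max_mismatch_frac)
        if merged is None:
            report["merge_failed"] += 1
            continue
        report["merged"] += 1
        if not filter_quality(merged.sequence, merged.quals, min_mean_q):
            report["quality_failed"] += 1
            continue
        report["quality_passed"] += 1
        result = trim_and_tag(merged.sequence, table)
        if isinstance(result, TrimFailure):
            report[f"discard_{result.reason.replace('-', '_')}"] += 1
            continue
        trimmed, iso = result
        mean_q = sum(merged.quals[: len(trimmed)]) / max(len(trimmed), 1)
        tagged.append((trimmed, iso, mean_q))
        report["tagged"] += 1
    unique = deduplicate(tagged)
    report["unique_sequences"] = len(unique)
    report["duplicate_count_total"] = sum(r.duplicate_count for r in unique)
    return unique, report
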