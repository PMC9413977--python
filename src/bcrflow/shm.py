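"""Somatic-hypermutation quantification.

Two views of SHM are computed:

* bulk: percent of aligned V-region nucleotides that differ from germline,
  per sequence, summarised per clone as a per-isotype median;
* single cell: mutations counted in a fixed window upstream of the CDR3
  (default the 280 positions from -300 to -21 relative to the CDR3 start,
  leaving a 20-nt guard before the junction), pooled over a cell's heavy
  and light chains as total mutations / total nucleotides counted, with a
  strict >1% cutoff flagging highly mutated cells.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotate import Rearrangement, SegmentAlignment
from .simulate import GermlineSegment

__all__ = [
    "WindowSpec",
    "ChainSHM",
    "CellSHM",
    "v_region_shm",
    "clone_median_shm",
    "chain_window_counts",
    "sc_window_shm",
    "fraction_high_shm",
    "HIGH_SHM_CUTOFF",
]

HIGH_SHM_CUTOFF = 0.01


@dataclass(frozen=True)
class WindowSpec:
    """Counting window upstream of the CDR3 start, in inclusive offsets.

    The default (-300 to -21) spans exactly 280 positions and never touches
    the CDR3 itself.
    """

    start_offset: int = 300  # nt upstream of CDR3 start (inclusive)
    end_offset: int = 21  # nt upstream of CDR3 start (inclusive)

    def __post_init__(self) -> None:
        if not (self.start_offset > self.end_offset >= 0):
            raise ValueError("require start_offset > end_offset >= 0")

    @property
    def length(self) -> int:
        return self.start_offset - self.end_offset + 1


@dataclass(frozen=True)
class ChainSHM:
    locus: str
    mutations: int
    counted_nt: int


@dataclass(frozen=True)
class CellSHM:
    cell_id: str
    chains: tuple[ChainSHM, ...]
    group: str | None = None

    @property
    def total_mutations(self) -> int:
        return sum(c.mutations for c in self.chains)

    @property
    def total_counted(self) -> int:
        return sum(c.counted_nt for c in self.chains)

    @property
    def combined_frequency(self) -> float | None:
        """Pooled mutations / pooled counted nt; None when nothing counted."""
        if self.total_counted == 0:
            return None
        return self.total_mutations / self.total_counted

    @property
    def high_shm(self) -> bool | None:
        """Strictly greater than the 1% cutoff; None when frequency missing."""
        f = self.combined_frequency
        return None if f is None else f > HIGH_SHM_CUTOFF


def v_region_shm(rearrangement: Rearrangement) -> float:
    """Percent of aligned V-region nucleotides mutated (gaps excluded)."""
    if rearrangement.v_aligned_length == 0:
        raise ValueError(f"{rearrangement.sequence_id}: no V alignment")
    return 100.0 * rearrangement.v_mutations / rearrangement.v_aligned_length


def clone_median_shm(
    members: Iterable[tuple[str, float]]
) -> dict[str, float]:
    """Median percent SHM per isotype over (isotype, percent) members."""
    by_iso: dict[str, list[float]] = {}
    for iso, pct in members:
        by_iso.setdefault(iso, []).append(pct)
    return {iso: statistics.median(vals) for iso, vals in by_iso.items()}


def chain_window_counts(
    sequence: str,
    cdr3_start: int,
    v_alignment: SegmentAlignment,
    germline: GermlineSegment,
    window: WindowSpec = WindowSpec(),
) -> tuple[int, int]:
    """Count (mutations, counted_nt) in the window for one chain.

    Window positions are taken on the chain sequence at
    ``[cdr3_start - start_offset, cdr3_start - end_offset]`` inclusive;
    only positions covered by the V alignment are counted, so a short
    sequence or truncated alignment yields fewer than ``window.length``
    counted positions rather than an exclusion.
    """
    lo = cdr3_start - window.start_offset
    hi = cdr3_start - window.end_offset  # inclusive
    mutations = 0
    counted = 0
    for (ts, te), (qs, qe) in v_alignment.blocks:
        for t in range(max(ts, lo), min(te, hi + 1)):
            if t < 0:
                continue
            g = qs + (t - ts)
            counted += 1
            if sequence[t] != germline.sequence[g]:
                mutations += 1
    return mutations, counted


def sc_window_shm(
    cell_id: str,
    chains: Sequence[tuple[str, str, int, SegmentAlignment, GermlineSegment]],
    window: WindowSpec = WindowSpec(),
    group: str | None = None,
) -> CellSHM:
    """Pool window mutation counts over a cell's chains.

    Each chain is ``(locus, sequence, cdr3_start, v_alignment, germline)``.
    A chain with zero counted positions contributes (0, 0); a cell with
    zero total counted positions has a missing combined frequency.
    """
    chain_counts = []
    for locus, sequence, cdr3_start, v_aln, germ in chains:
        m, n = chain_window_counts(sequence, cdr3_start, v_aln, germ, window)
        chain_counts.append(ChainSHM(locus=locus, mutations=m, counted_nt=n))
    return CellSHM(cell_id=cell_id, chains=tuple(chain_counts), group=group)


def fraction_high_shm(
    cells: Iterable[CellSHM],
    groups: Mapping[str, str] | None = None,
) -> dict[str, float | None]:
    """Per-group fraction of non-missing cells above the strict 1% cutoff.

    Groups come from ``groups`` (cell_id -> label) or each cell's own
    ``group``; cells with no label fall into ``"all"``.  A group whose
    cells are all missing yields None, not zero.
    """
    tally: dict[str, list[bool]] = {}
    for cell in cells:
        label = (groups or {}).get(cell.cell_id, cell.group) or "all"
        tally.setdefault(label, [])
        if cell.high_shm is not None:
            tally[label].append(cell.high_shm)
    return {
        label: (sum(flags) / len(flags) if flags else None)
        for label, flags in tally.items()
    }
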