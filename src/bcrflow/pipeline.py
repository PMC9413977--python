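"""End-to-end conveniences chaining the analysis stages.

These helpers connect the simulator's outputs to annotation, clone
inference and SHM quantification without the caller shuttling
intermediate objects around; each stage remains usable on its own.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .annotate import Rearrangement, ScoringParams, annotate_sequence
from .clones import Clone, build_clones
from .preprocess import ProcessedSequence
from .shm import CellSHM, WindowSpec, sc_window_shm
from .simulate import GermlineSegment, TrueRearrangement

__all__ = [
    "annotate_processed",
    "annotate_truth",
    "infer_clones",
    "sc_cell_shm",
    "rearrangements_to_airr",
]


def annotate_processed(
    processed: Sequence[ProcessedSequence],
    library: Sequence[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
) -> tuple[list[Rearrangement], int]:
    """Annotate deduplicated sequences; returns (annotated, n_unassignable)."""
    out = []
    unassignable = 0
    for i, rec in enumerate(processed):
        r = annotate_sequence(
            sequence_id=f"U{i:06d}",
            sequence=rec.sequence,
            library=library,
            scoring=scoring,
            isotype=rec.isotype,
            duplicate_count=rec.duplicate_count,
        )
        if r is None:
            unassignable += 1
        else:
            out.append(r)
    return out, unassignable


def annotate_truth(
    rearrangements: Sequence[TrueRearrangement],
    library: Sequence[GermlineSegment],
    scoring: ScoringParams = ScoringParams(),
) -> tuple[list[Rearrangement], int]:
    """Annotate simulator truth sequences directly (no read stage)."""
    out = []
    unassignable = 0
    for t in rearrangements:
        r = annotate_sequence(
            sequence_id=t.sequence_id,
            sequence=t.full_sequence,
            library=library,
            scoring=scoring,
            isotype=t.isotype,
        )
        if r is None:
            unassignable += 1
        else:
            out.append(r)
    return out, unassignable


def infer_clones(
    rearrangements: Sequence[Rearrangement], threshold: float = 0.9
) -> tuple[list[Clone], dict[str, str]]:
    """QC-passing rearrangements only; thin wrapper over clone building."""
    passing = [r for r in rearrangements if r.cdr3_nt is not None]
    return build_clones(passing, threshold=threshold)


def sc_cell_shm(
    contigs: pd.DataFrame,
    libraries: Mapping[str, Sequence[GermlineSegment]],
    window: WindowSpec = WindowSpec(),
    scoring: ScoringParams = ScoringParams(),
) -> list[CellSHM]:
    """Annotate each chain of a contig table and pool window SHM per cell.

    Chains that cannot be annotated or lack a CDR3 contribute (0, 0)
    counted positions, mirroring the treatment of uncovered windows.
    """
    by_name = {
        s.name: s for lib in libraries.values() for s in lib
    }
    cells: list[CellSHM] = []
    for cell_id, sub in contigs.groupby("cell_id", sort=True):
        chains = []
        group = sub["subset"].iloc[0] if "subset" in sub else None
        for row in sub.itertuples():
            rearr = annotate_sequence(
                sequence_id=f"{cell_id}:{row.locus}",
                sequence=row.sequence,
                library=list(libraries[row.locus]),
                scoring=scoring,
            )
            if rearr is None or rearr.cdr3_start is None:
                continue
            chains.append(
                (
                    row.locus,
                    row.sequence,
                    rearr.cdr3_start,
                    rearr.v_alignment,
                    by_name[rearr.v_call],
                )
            )
        cells.append(sc_window_shm(cell_id, chains, window=window, group=group))
    return cells


def rearrangements_to_airr(rearrangements: Sequence[Rearrangement]) -> pd.DataFrame:
    """AIRR-style rearrangement table for annotated sequences."""
    return pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "sequence": r.sequence,
                "v_call": r.v_call,
                "j_call": r.j_call,
                "junction": r.cdr3_nt,
                "cdr3": r.cdr3_imgt,
                "cdr3_start": r.cdr3_start,
                "cdr3_end": r.cdr3_end,
                "v_identity": r.v_identity,
                "c_call": r.isotype,
                "duplicate_count": r.duplicate_count,
            }
            for r in rearrangements
        ]
    )
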