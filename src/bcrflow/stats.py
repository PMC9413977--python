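"""Repertoire-level summaries.

Diversity is reported as Hill numbers (q=0 richness, q=1 exponential
Shannon entropy, q=2 inverse Simpson) and D20 (mass fraction of the 20
largest clones).  Single-cell summaries cover clonotype grouping on exact
heavy/light junction (or CDR3) identity, the expanded-clonotype fraction,
the fraction of cells with 3-4 consensus chains, and isotype-class
frequencies per cell subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CellVDJ",
    "Clonotype",
    "MultichainSummary",
    "hill_diversity",
    "d20",
    "usage_tables",
    "sc_clonotypes",
    "multichain_fraction",
    "isotype_by_subset",
    "cells_from_airr",
]

UNSWITCHED = {"IGHM", "IGHD"}
IGG = {"IGHG1", "IGHG2", "IGHG3", "IGHG4"}
IGA = {"IGHA1", "IGHA2"}


@dataclass(frozen=True)
class Chain:
    locus: str
    junction_nt: str
    cdr3_nt: str
    isotype: str | None = None
    duplicate_count: int = 1


@dataclass(frozen=True)
class CellVDJ:
    cell_id: str
    chains: tuple[Chain, ...]
    subset: str | None = None  # CD11c_pos | CD11c_neg
    donor: str | None = None

    @property
    def heavy_isotype(self) -> str | None:
        h = _representative(self.chains, {"IGH"})
        return h.isotype if h else None


@dataclass
class Clonotype:
    clonotype_id: str
    key: tuple[str, str]
    member_cells: list[str] = field(default_factory=list)

    @property
    def expanded(self) -> bool:
        return len(self.member_cells) >= 2


@dataclass(frozen=True)
class MultichainSummary:
    n_cells: int
    fraction_3_4: float
    n_over_4: int


def hill_diversity(clone_sizes: Sequence[float], q: float) -> float:
    """Hill number of order q on clone-size proportions.

    q=0 is richness; q=1 is taken as the Shannon limit exp(H); other q use
    (sum p^q)^(1/(1-q)).
    """
    sizes = [float(s) for s in clone_sizes]
    if not sizes:
        raise ValueError("empty repertoire")
    if any(s <= 0 for s in sizes):
        raise ValueError("clone sizes must be positive")
    if q < 0:
        raise ValueError("q must be >= 0")
    total = sum(sizes)
    p = [s / total for s in sizes]
    if q == 0:
        return float(len(p))
    if abs(q - 1.0) < 1e-12:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x**q for x in p) ** (1.0 / (1.0 - q))


def d20(clone_sizes: Sequence[float], clone_ids: Sequence[str] | None = None) -> float:
    """Fraction of total repertoire size held by the 20 largest clones.

    Ties at the cut are broken by clone id; fewer than 20 clones yields 1.0.
    """
    if not clone_sizes:
        raise ValueError("empty repertoire")
    ids = clone_ids if clone_ids is not None else [str(i) for i in range(len(clone_sizes))]
    ranked = sorted(zip(clone_sizes, ids), key=lambda t: (-t[0], t[1]))
    total = sum(s for s, _ in ranked)
    top = sum(s for s, _ in ranked[:20])
    return top / total


def usage_tables(
    labels: Iterable[str] | Iterable[Sequence[str]],
    weights: Iterable[float] | None = None,
) -> pd.Series:
    """Frequency table over V genes or isotype subclasses, summing to 1.

    Each item may be one label (a rearrangement's gene / subclass) or a
    collection of labels (a clone's subclass set: the clone counts once per
    subclass it contains).  ``weights`` scale each item's contribution
    (e.g. duplicate counts for total-read weighting).
    """
    counts: dict[str, float] = {}
    items = list(labels)
    w = list(weights) if weights is not None else [1.0] * len(items)
    if len(w) != len(items):
        raise ValueError("weights length mismatch")
    for item, wt in zip(items, w):
        if isinstance(item, str):
            item = [item]
        for label in item:
            counts[label] = counts.get(label, 0.0) + wt
    total = sum(counts.values())
    if total == 0:
        raise ValueError("nothing to tabulate")
    return pd.Series({k: v / total for k, v in sorted(counts.items())}, name="frequency")


def _representative(chains: Sequence[Chain], loci: set[str]) -> Chain | None:
    """Most-supported chain among the given loci (ties lexicographic)."""
    candidates = [c for c in chains if c.locus in loci]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-c.duplicate_count, c.junction_nt))


def sc_clonotypes(
    cells: Sequence[CellVDJ], key_mode: str = "junction"
) -> tuple[list[Clonotype], float | None]:
    """Group cells into clonotypes on exact heavy+light sequence identity.

    Each cell is reduced to one heavy and one light representative chain
    (highest duplicate_count; ties lexicographic by junction); cells
    lacking either locus are excluded.  ``key_mode`` selects the junction
    or the CDR3 as the identity key.  Returns the clonotypes and the
    expanded fraction (clonotypes with >= 2 cells / total clonotypes; None
    when no cell could be paired).
    """
    if key_mode not in ("junction", "cdr3"):
        raise ValueError("key_mode must be 'junction' or 'cdr3'")
    groups: dict[tuple[str, str], list[str]] = {}
    for cell in sorted(cells, key=lambda c: c.cell_id):
        heavy = _representative(cell.chains, {"IGH"})
        light = _representative(cell.chains, {"IGK", "IGL"})
        if heavy is None or light is None:
            continue
        if key_mode == "junction":
            key = (heavy.junction_nt, light.junction_nt)
        else:
            key = (heavy.cdr3_nt, light.cdr3_nt)
        groups.setdefault(key, []).append(cell.cell_id)
    clonotypes = [
        Clonotype(clonotype_id=f"CT{i:05d}", key=key, member_cells=members)
        for i, (key, members) in enumerate(sorted(groups.items()))
    ]
    if not clonotypes:
        return [], None
    expanded = sum(ct.expanded for ct in clonotypes) / len(clonotypes)
    return clonotypes, expanded


def multichain_fraction(cells: Sequence[CellVDJ]) -> MultichainSummary:
    """Fraction of cells carrying 3-4 consensus chains; >4 counted apart."""
    if not cells:
        raise ValueError("no cells")
    n34 = sum(1 for c in cells if len(c.chains) in (3, 4))
    over = sum(1 for c in cells if len(c.chains) > 4)
    return MultichainSummary(
        n_cells=len(cells), fraction_3_4=n34 / len(cells), n_over_4=over
    )


def isotype_by_subset(cells: Sequence[CellVDJ]) -> pd.DataFrame:
    """Per-subset frequencies of unswitched / IgG / IgA1-2 / IgE classes.

    Frequencies over the four classes sum to 1 per subset; IgA1 and IgA2
    are additionally reported separately.  Subsets with no classified cell
    are omitted.
    """
    rows = {}
    for subset in sorted({c.subset for c in cells if c.subset is not None}):
        isotypes = [
            c.heavy_isotype
            for c in cells
            if c.subset == subset and c.heavy_isotype is not None
        ]
        if not isotypes:
            continue
        n = len(isotypes)
        rows[subset] = {
            "n_cells": n,
            "unswitched": sum(i in UNSWITCHED for i in isotypes) / n,
            "IgG": sum(i in IGG for i in isotypes) / n,
            "IgA1_2": sum(i in IGA for i in isotypes) / n,
            "IgE": sum(i == "IGHE" for i in isotypes) / n,
            "IgA1": sum(i == "IGHA1" for i in isotypes) / n,
            "IgA2": sum(i == "IGHA2" for i in isotypes) / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cells_from_airr(df: pd.DataFrame) -> list[CellVDJ]:
    """Build CellVDJ objects from an AIRR-style chain table."""
    cells = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        chains = tuple(
            Chain(
                locus=row.locus,
                junction_nt=row.junction,
                cdr3_nt=row.cdr3,
                isotype=row.c_call if row.locus == "IGH" else None,
                duplicate_count=int(row.duplicate_count),
            )
            for row in sub.itertuples()
        )
        subset = sub["subset"].iloc[0] if "subset" in sub else None
        donor = sub["donor"].iloc[0] if "donor" in sub else None
        cells.append(CellVDJ(cell_id=cell_id, chains=chains, subset=subset, donor=donor))
    return cells
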