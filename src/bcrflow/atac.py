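"""Differential chromatin-accessibility calls and T-bet-dependence set logic.

A simple differential caller (library-size-normalised log2 counts, Welch
t-test per locus, Benjamini-Hochberg correction, fold-change floor) feeds a
set-logic layer: a locus whose stimulation-induced change in control cells
is significant, but not significant in T-bet-deficient (mutant) cells, is
classed T-bet-dependent; a locus significant in both genotypes is
T-bet-independent; a locus not significant in control is not differential.
Overlap and stage summaries report counts with integer percentages rounded
half-up, matching the usual printed style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_call",
    "classify_dependence",
    "overlap_summary",
    "stage_summary",
    "OverlapSummary",
    "StageSummary",
    "round_half_up_pct",
]

DEPENDENCE_CLASSES = ("tbet_dependent", "tbet_independent", "not_differential")


def round_half_up_pct(numerator: float, denominator: float) -> int | None:
    """100 * numerator / denominator rounded half-up; None on empty denom."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def differential_call(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    baseline: str = "unstim",
    treatment: str = "stim",
) -> pd.DataFrame:
    """Per-locus differential calls of treatment vs baseline.

    ``counts`` is long-form with columns locus_id, group, replicate, count
    (group in {baseline, treatment}, >= 2 replicates each).  Counts are
    library-size normalised, log2(x + 0.5) transformed, tested per locus
    with a two-sided Welch t-test and BH-corrected across loci; a locus is
    significant iff adjusted p < alpha and \\|log2FC\\| >= min_lfc.

    Returns a DataFrame indexed by locus_id with columns log2_fc, pvalue,
    padj, significant, direction (up/down/unchanged).
    """
    required = {"locus_id", "group", "replicate", "count"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    wide = counts.pivot_table(
        index="locus_id", columns=["group", "replicate"], values="count"
    )
    if wide.isna().any().any():
        raise ValueError("ragged count table: every locus needs every sample")
    for group in (baseline, treatment):
        if group not in wide.columns.get_level_values(0):
            raise ValueError(f"missing group {group!r}")
        if wide[group].shape[1] < 2:
            raise ValueError(f"group {group!r} needs >= 2 replicates")
    libsize = wide.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("a sample has zero total counts")
    norm = wide / libsize * libsize.mean()
    log = np.log2(norm + 0.5)
    a = log[treatment].to_numpy()
    b = log[baseline].to_numpy()
    _, pvals = sps.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    padj = multipletests(pvals, method="fdr_bh")[1]
    significant = (padj < alpha) & (np.abs(lfc) >= min_lfc)
    direction = np.where(significant, np.where(lfc > 0, "up", "down"), "unchanged")
    return pd.DataFrame(
        {
            "log2_fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "significant": significant,
            "direction": direction,
        },
        index=wide.index,
    )


def classify_dependence(
    ctrl_calls: pd.DataFrame, mut_calls: pd.DataFrame
) -> pd.DataFrame:
    """Class per locus from paired control / mutant differential calls.

    tbet_dependent: significant in control, not in mutant;
    tbet_independent: significant in both; not_differential: not
    significant in control.  Both call tables must cover the same loci.
    """
    missing = sorted(set(ctrl_calls.index) ^ set(mut_calls.index))
    if missing:
        raise ValueError(f"loci present in only one genotype: {missing[:10]}")
    ctrl = ctrl_calls.sort_index()
    mut = mut_calls.loc[ctrl.index]
    cls = np.where(
        ~ctrl["significant"],
        "not_differential",
        np.where(mut["significant"], "tbet_independent", "tbet_dependent"),
    )
    return pd.DataFrame(
        {
            "dependence_class": cls,
            "ctrl_direction": ctrl["direction"],
            "mut_significant": mut["significant"].to_numpy(),
        },
        index=ctrl.index,
    )


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_intersection: int
    pct_of_a: int | None  # 100 * |A∩B| / |A|, rounded half-up
    pct_of_b: int | None


def overlap_summary(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapSummary:
    """Counts and integer-rounded percentages for two locus-id sets."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_intersection=inter,
        pct_of_a=round_half_up_pct(inter, len(a)),
        pct_of_b=round_half_up_pct(inter, len(b)),
    )


@dataclass(frozen=True)
class StageSummary:
    n_up: int
    n_down: int
    total_differential: int
    n_unaltered_in_mutant: int | None
    pct_unaltered_in_mutant: int | None


def stage_summary(
    n_up: int, n_down: int, n_unaltered_in_mutant: int | None = None
) -> StageSummary:
    """Totals and retained percentages for one stimulation comparison."""
    total = n_up + n_down
    pct = (
        round_half_up_pct(n_unaltered_in_mutant, total)
        if n_unaltered_in_mutant is not None
        else None
    )
    return StageSummary(
        n_up=n_up,
        n_down=n_down,
        total_differential=total,
        n_unaltered_in_mutant=n_unaltered_in_mutant,
        pct_unaltered_in_mutant=pct,
    )
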