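"""Clone inference: V/J/CDR3-length partition + 90% CDR3 identity clustering.

Sequences are first partitioned on (V gene, J gene, CDR3 length); within a
partition, equal-length CDR3 nucleotide sequences are clustered greedily
around abundance-sorted centroids (CD-HIT style) at a configurable identity
threshold, identity being Hamming-based since lengths are equal.  Each
cluster is one inferred clone, sized both as unique sequences and as total
reads, with per-isotype median SHM summaries.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotate import Rearrangement

__all__ = ["Clone", "partition", "cluster_cdr3", "build_clones", "hamming_identity"]

DEFAULT_THRESHOLD = 0.9


def hamming_identity(a: str, b: str) -> float:
    """(length - Hamming distance) / length for equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    mism = sum(x != y for x, y in zip(a, b))
    return (len(a) - mism) / len(a)


def gene_level(call: str) -> str:
    """Collapse an allele-level call (e.g. ``IGHV-sim-01*02``) to gene level."""
    return call.split("*", 1)[0]


def partition(
    rearrangements: Sequence[Rearrangement],
) -> dict[tuple[str, str, int], list[Rearrangement]]:
    """Exact partition on (V gene, J gene, CDR3 length)."""
    out: dict[tuple[str, str, int], list[Rearrangement]] = {}
    for r in rearrangements:
        if r.cdr3_nt is None:
            raise ValueError(f"{r.sequence_id}: no CDR3; run qc_filter first")
        key = (gene_level(r.v_call), gene_level(r.j_call), len(r.cdr3_nt))
        out.setdefault(key, []).append(r)
    return out


def cluster_cdr3(
    cdr3s: Sequence[str],
    abundances: Sequence[int] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[int]:
    """Greedy abundance-sorted centroid clustering of equal-length CDR3s.

    Sequences are processed in descending abundance (ties lexicographic by
    sequence, then input position); each joins the first existing centroid
    with identity >= ``threshold``, else founds a new centroid.  Returns a
    cluster index per input position; the ordering rules make the result
    independent of input order.
    """
    if not cdr3s:
        return []
    lengths = {len(c) for c in cdr3s}
    if len(lengths) > 1:
        raise ValueError("all CDR3s in one clustering call must share a length")
    if abundances is None:
        abundances = [1] * len(cdr3s)
    order = sorted(range(len(cdr3s)), key=lambda i: (-abundances[i], cdr3s[i], i))
    centroids: list[str] = []
    assignment = [0] * len(cdr3s)
    for i in order:
        seq = cdr3s[i]
        for k, centroid in enumerate(centroids):
            if hamming_identity(seq, centroid) >= threshold:
                assignment[i] = k
                break
        else:
            centroids.append(seq)
            assignment[i] = len(centroids) - 1
    return assignment


@dataclass
class Clone:
    """A set of rearrangements inferred to share a progenitor B cell."""

    clone_id: str
    v_gene: str
    j_gene: str
    cdr3_length: int
    centroid_cdr3: str
    members: list[str] = field(default_factory=list)  # sequence_ids
    size_unique: int = 0
    size_total: int = 0
    median_shm_by_isotype: dict[str, float] = field(default_factory=dict)


def build_clones(
    rearrangements: Sequence[Rearrangement],
    threshold: float = DEFAULT_THRESHOLD,
    shm_by_id: Mapping[str, float] | None = None,
) -> tuple[list[Clone], dict[str, str]]:
    """Infer clones; returns (clones, sequence_id -> clone_id membership).

    ``shm_by_id`` maps sequence_id to percent V-region SHM; when omitted it
    is derived from each rearrangement's V identity.  Per-clone medians are
    computed per isotype over the members carrying that isotype.
    """
    parts = partition(rearrangements)
    clones: list[Clone] = []
    membership: dict[str, str] = {}
    for (v, j, length), members in sorted(parts.items()):
        cdr3s = [m.cdr3_nt for m in members]
        abundances = [m.duplicate_count for m in members]
        assignment = cluster_cdr3(cdr3s, abundances, threshold)
        n_clusters = max(assignment) + 1
        # centroid = founder = first-processed member of the cluster
        order = sorted(
            range(len(members)), key=lambda i: (-abundances[i], cdr3s[i], i)
        )
        centroid: dict[int, str] = {}
        for i in order:
            centroid.setdefault(assignment[i], cdr3s[i])
        for k in range(n_clusters):
            idx = [i for i in range(len(members)) if assignment[i] == k]
            clone_id = f"{v}|{j}|{length}|{k}"
            shm_vals: dict[str, list[float]] = {}
            for i in idx:
                m = members[i]
                membership[m.sequence_id] = clone_id
                if shm_by_id is not None:
                    pct = shm_by_id.get(m.sequence_id)
                else:
                    pct = 100.0 * (1.0 - m.v_identity)
                if pct is not None and m.isotype is not None:
                    shm_vals.setdefault(m.isotype, []).append(pct)
            clones.append(
                Clone(
                    clone_id=clone_id,
                    v_gene=v,
                    j_gene=j,
                    cdr3_length=length,
                    centroid_cdr3=centroid[k],
                    members=[members[i].sequence_id for i in idx],
                    size_unique=len(idx),
                    size_total=sum(members[i].duplicate_count for i in idx),
                    median_shm_by_isotype={
                        iso: statistics.median(vals) for iso, vals in shm_vals.items()
                    },
                )
            )
    return clones, membership
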