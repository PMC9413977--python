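"""Synthetic BCR repertoires, reads, single-cell contigs and accessibility counts.

Everything downstream of this module (read preprocessing, V/J annotation,
clone inference, SHM quantification, repertoire statistics, differential
accessibility) is exercised against data generated here, with the planted
ground truth carried alongside so parameter-recovery can be asserted.

The model is deliberately minimal but structurally faithful:

* A toy germline library of V and J segments.  Every V ends in a conserved
  cysteine codon (TGT/TGC) preceded by 300 nt of framework, so the
  280-nt mutation-counting window upstream of CDR3 is always fully covered.
  Every J carries the conserved tryptophan (heavy) or phenylalanine (light)
  anchor near its 5' end.
* Clonally structured repertoires: each clone owns one fixed junction
  (V anchor + N region + J anchor); members accumulate independent uniform
  point mutations at a configurable per-site rate and draw an isotype
  subclass from a configurable probability table.
* Paired 2x300 amplicon reads with PCR duplicates, a truncated-normal
  Phred model, and the constant-region primer as the first bases of read 2.
* Cell-barcoded paired heavy/light contig tables with occasional extra
  chains, a CD11c subset label, and planted window mutation counts.
* Negative-binomial accessibility count tables with planted locus classes
  for the stimulation-vs-genotype set logic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GermlineSegment",
    "SimulationConfig",
    "TrueRearrangement",
    "DEFAULT_ISOTYPE_PROBS",
    "DEFAULT_PRIMERS",
    "IGA_PRIMER",
    "IGE_PRIMER",
    "build_germline_library",
    "simulate_repertoire",
    "emit_bulk_reads",
    "emit_sc_contigs",
    "simulate_atac_counts",
    "revcomp",
]

CHAINS = ("IGH", "IGK", "IGL")
BASES = np.array(list("ACGT"))

#: Published constant-region reverse primers (55 nt: a 34-nt sequencing tail
#: followed by the 21-nt constant-region-specific part).
IGA_PRIMER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAGCAGGTCACACTGAGTGGCTCC"
IGE_PRIMER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAGCCAGGCAGCCCAGAGTCACGG"

_PRIMER_TAIL = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

#: Per-subclass primer table.  IgA1 and IgE use the published primers; the
#: remaining subclasses use synthetic primers built in the same style (shared
#: 34-nt tail + a distinct 21-nt constant-region part) so each subclass is
#: taggable by exact match.
DEFAULT_PRIMERS: dict[str, str] = {
    "IGHM": _PRIMER_TAIL + "GGGAATTCTCACAGGAGACGA",
    "IGHD": _PRIMER_TAIL + "CACATCCGGAGCCTTGGTGGG",
    "IGHG1": _PRIMER_TAIL + "GGGAAGACCGATGGGCCCTTG",
    "IGHG2": _PRIMER_TAIL + "CTGGGCATGTACGTCCAGCGG",
    "IGHG3": _PRIMER_TAIL + "TGGTGAGCTCAGCGGGAAGTA",
    "IGHG4": _PRIMER_TAIL + "CCGCTGTGCCCATCTGTCTCA",
    "IGHA1": IGA_PRIMER,
    "IGHA2": _PRIMER_TAIL + "GAGGCTCAGCGGGAAGACCTT",
    "IGHE": IGE_PRIMER,
}

#: Realistic peripheral-blood subclass mix used as the simulator default.
DEFAULT_ISOTYPE_PROBS: dict[str, float] = {
    "IGHM": 0.35,
    "IGHD": 0.05,
    "IGHG1": 0.20,
    "IGHG2": 0.12,
    "IGHG3": 0.04,
    "IGHG4": 0.02,
    "IGHA1": 0.15,
    "IGHA2": 0.05,
    "IGHE": 0.02,
}

# Framework length upstream of the V anchor codon; 300 nt guarantees the
# 280-nt window (-300..-21 from CDR3 start) is always fully covered.
V_UPSTREAM = 300
# J layout: 9 nt 5' of the anchor codon (inside CDR3), then 36 nt of FR4.
J_PRE_ANCHOR = 9
J_POST_ANCHOR = 36
# Allowed N-region lengths (multiples of 3 keep the junction in frame).
N_LENGTHS = (0, 3, 6, 9, 12, 15)
# Planted junctions within one (V, J, length) group are rejected until their
# pairwise identity is at most this, keeping planted clones separable at the
# 90% clustering threshold even after light SHM.
MAX_PLANTED_JUNCTION_IDENTITY = 0.85


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GermlineSegment:
    """A reference V or J gene with its conserved CDR3 anchor codon.

    ``anchor`` is the 0-based offset of the first base of the anchor codon
    (Cys TGT/TGC for V segments; Trp TGG for heavy J, Phe TTT/TTC for light
    J) and lies on a codon boundary of the segment's declared reading frame.
    """

    name: str
    segment_class: str  # "V" or "J"
    chain: str  # IGH | IGK | IGL
    sequence: str
    anchor: int
    frame: int = 0

    def __post_init__(self) -> None:
        if self.segment_class not in ("V", "J"):
            raise ValueError(f"segment_class must be V or J, got {self.segment_class!r}")
        if not (0 <= self.anchor <= len(self.sequence) - 3):
            raise ValueError("anchor codon outside sequence bounds")
        if (self.anchor - self.frame) % 3 != 0:
            raise ValueError("anchor not on a codon boundary")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence contains non-ACGT characters")


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` fully determines every output."""

    seed: int = 0
    n_clones: int = 50
    n_sequences: int | None = None  # exact repertoire size; None -> Zipf draw
    clone_size_law: float = 1.5  # Zipf exponent for clone sizes
    shm_rate: float = 0.02  # per-site substitution probability per member
    isotype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOTYPE_PROBS)
    )
    n_cells: int = 500
    multichain_rate: float = 0.05  # P(cell carries 3-4 consensus chains)
    cd11c_pos_rate: float = 0.5
    isotype_probs_by_subset: Mapping[str, Mapping[str, float]] | None = None
    read_length: int = 300
    mean_q: float = 32.0
    q_sd: float = 4.0
    duplicate_lambda: float = 1.0  # mean extra PCR copies per molecule
    seq_error_rate: float = 0.0  # uniform per-base substitution in reads

    def validate(self) -> None:
        _check_probs(self.isotype_probs, "isotype_probs")
        if self.isotype_probs_by_subset is not None:
            for subset, probs in self.isotype_probs_by_subset.items():
                _check_probs(probs, f"isotype_probs_by_subset[{subset}]")
        if not (0.0 <= self.shm_rate <= 0.3):
            raise ValueError(f"shm_rate must be in [0, 0.3], got {self.shm_rate}")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not (0.0 <= self.multichain_rate <= 1.0):
            raise ValueError("multichain_rate must be a probability")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _check_probs(probs: Mapping[str, float], what: str) -> None:
    if not probs:
        raise ValueError(f"{what} is empty")
    total = float(sum(probs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {total:.12f})")


@dataclass(frozen=True)
class TrueRearrangement:
    """Ground truth for one simulated sequence."""

    sequence_id: str
    clone_id: str
    v_name: str
    j_name: str
    junction_nt: str  # includes both anchor codons
    full_sequence: str  # after SHM
    mutated_positions: tuple[tuple[int, str, str], ...]
    isotype: str

    @property
    def germline_sequence(self) -> str:
        """Reconstruct the unmutated sequence from the recorded mutations."""
        seq = list(self.full_sequence)
        for pos, ref, _alt in self.mutated_positions:
            seq[pos] = ref
        return "".join(seq)


# ---------------------------------------------------------------------------
# germline library


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def build_germline_library(
    seed: int, n_v: int, n_j: int, chain: str
) -> list[GermlineSegment]:
    """Generate a deterministic toy germline library for one chain.

    V segments are 303 nt: 300 nt of framework followed by a terminal
    TGT/TGC cysteine anchor codon.  J segments are 48 nt with the anchor
    codon (TGG for IGH, TTT/TTC for light chains) at offset 9.
    """
    if chain not in CHAINS:
        raise ValueError(f"unknown chain {chain!r}; allowed: {', '.join(CHAINS)}")
    if n_v < 1 or n_j < 1:
        raise ValueError("n_v and n_j must each be >= 1")
    rng = np.random.default_rng([abs(int(seed)), CHAINS.index(chain), n_v, n_j])
    segments: list[GermlineSegment] = []
    for i in range(n_v):
        cys = "TGT" if rng.random() < 0.5 else "TGC"
        seq = _random_seq(rng, V_UPSTREAM) + cys
        segments.append(
            GermlineSegment(
                name=f"{chain}V-sim-{i + 1:02d}",
                segment_class="V",
                chain=chain,
                sequence=seq,
                anchor=V_UPSTREAM,
            )
        )
    j_anchors = ("TGG",) if chain == "IGH" else ("TTT", "TTC")
    for i in range(n_j):
        anchor_codon = j_anchors[int(rng.integers(len(j_anchors)))]
        seq = (
            _random_seq(rng, J_PRE_ANCHOR)
            + anchor_codon
            + _random_seq(rng, J_POST_ANCHOR)
        )
        segments.append(
            GermlineSegment(
                name=f"{chain}J-sim-{i + 1:02d}",
                segment_class="J",
                chain=chain,
                sequence=seq,
                anchor=J_PRE_ANCHOR,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# repertoire


def _identity(a: str, b: str) -> float:
    mism = sum(x != y for x, y in zip(a, b))
    return (len(a) - mism) / len(a)


def _make_junction(
    rng: np.random.Generator,
    v: GermlineSegment,
    j: GermlineSegment,
    existing: dict[tuple[str, str, int], list[str]],
) -> str:
    """Draw a junction (V anchor + N + J anchor region) for a new clone.

    Rejection-sampled so planted clones sharing a (V, J, length) group stay
    below ``MAX_PLANTED_JUNCTION_IDENTITY`` pairwise CDR3 identity; the
    planted partition is then recoverable at the 90% threshold.
    """
    v_part = v.sequence[v.anchor : v.anchor + 3]
    j_part = j.sequence[: j.anchor + 3]
    for _ in range(500):
        n_len = int(rng.choice(N_LENGTHS))
        junction = v_part + _random_seq(rng, n_len) + j_part
        key = (v.name, j.name, len(junction))
        if all(
            _identity(junction, other) <= MAX_PLANTED_JUNCTION_IDENTITY
            for other in existing.get(key, [])
        ):
            existing.setdefault(key, []).append(junction)
            return junction
    raise RuntimeError("could not place a sufficiently distinct junction")


def _clone_sizes(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Clone sizes under a Zipf law; exact total when n_sequences is set."""
    a = config.clone_size_law
    if config.n_sequences is None:
        return np.minimum(rng.zipf(a, size=config.n_clones), 10_000)
    n, k = config.n_sequences, config.n_clones
    if n < k:
        raise ValueError("n_sequences must be >= n_clones")
    weights = 1.0 / np.arange(1, k + 1) ** a
    weights /= weights.sum()
    extra = rng.multinomial(n - k, weights)
    sizes = 1 + extra
    return rng.permutation(sizes)


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protected: range | None = None
) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """Uniform per-site substitutions; positions in ``protected`` are skipped."""
    if rate <= 0.0:
        return seq, ()
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if protected is not None and hits.size:
        hits = hits[(hits < protected.start) | (hits >= protected.stop)]
    muts = []
    for pos in hits:
        ref = arr[pos]
        alt = rng.choice(BASES[BASES != ref])
        arr[pos] = alt
        muts.append((int(pos), str(ref), str(alt)))
    return "".join(arr), tuple(muts)


def simulate_repertoire(
    config: SimulationConfig, library: Sequence[GermlineSegment]
) -> list[TrueRearrangement]:
    """Simulate a clonally structured repertoire from a germline library.

    Each clone owns one fixed junction; members mutate independently at
    ``shm_rate`` per site over the whole sequence and draw an isotype from
    ``isotype_probs``.
    """
    config.validate()
    vs = sorted((s for s in library if s.segment_class == "V"), key=lambda s: s.name)
    js = sorted((s for s in library if s.segment_class == "J"), key=lambda s: s.name)
    if not vs or not js:
        raise ValueError("library must contain at least one V and one J segment")
    rng = np.random.default_rng([abs(int(config.seed)), 1])
    sizes = _clone_sizes(rng, config)
    isotypes = sorted(config.isotype_probs)
    iso_p = np.array([config.isotype_probs[i] for i in isotypes])
    iso_p = iso_p / iso_p.sum()
    junctions_seen: dict[tuple[str, str, int], list[str]] = {}
    out: list[TrueRearrangement] = []
    seq_idx = 0
    for c, size in enumerate(sizes):
        v = vs[int(rng.integers(len(vs)))]
        j = js[int(rng.integers(len(js)))]
        junction = _make_junction(rng, v, j, junctions_seen)
        germline = v.sequence[: v.anchor] + junction + j.sequence[j.anchor + 3 :]
        clone_id = f"C{c:04d}"
        for _ in range(int(size)):
            mutated, muts = _mutate(rng, germline, config.shm_rate)
            iso = isotypes[int(rng.choice(len(isotypes), p=iso_p))]
            out.append(
                TrueRearrangement(
                    sequence_id=f"S{seq_idx:06d}",
                    clone_id=clone_id,
                    v_name=v.name,
                    j_name=j.name,
                    junction_nt=junction,
                    full_sequence=mutated,
                    mutated_positions=muts,
                    isotype=iso,
                )
            )
            seq_idx += 1
    return out


# ---------------------------------------------------------------------------
# bulk reads


@dataclass(frozen=True)
class SimulatedReadPair:
    """One emitted read pair; ids encode molecule and duplicate index."""

    id: str
    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]


def _phred(rng: np.random.Generator, n: int, mean_q: float, q_sd: float) -> np.ndarray:
    q = np.rint(rng.normal(mean_q, q_sd, size=n)).astype(int)
    return np.clip(q, 2, 41)


def _seq_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    out, _ = _mutate(rng, seq, rate)
    return out


def emit_bulk_reads(
    rearrangements: Sequence[TrueRearrangement],
    config: SimulationConfig,
    primers: Mapping[str, str] = DEFAULT_PRIMERS,
) -> tuple[list[SimulatedReadPair], pd.DataFrame]:
    """Emit paired amplicon reads with PCR duplicates.

    The sense-strand amplicon is the rearranged sequence followed by the
    reverse complement of the isotype's constant-region primer, so read 2
    (sequenced from the constant-region side) begins with the primer exactly
    as printed.  Read pairs overlap in the middle of the amplicon, letting
    overlap merging reconstruct it.

    Returns the read pairs plus a duplicate ledger (one row per molecule:
    sequence_id, isotype, n_reads).
    """
    config.validate()
    missing = sorted({r.isotype for r in rearrangements} - set(primers))
    if missing:
        raise ValueError(f"no primer configured for isotypes: {', '.join(missing)}")
    rng = np.random.default_rng([abs(int(config.seed)), 2])
    L = config.read_length
    pairs: list[SimulatedReadPair] = []
    ledger_rows = []
    for r in rearrangements:
        amplicon = r.full_sequence + revcomp(primers[r.isotype])
        n_reads = 1 + int(rng.poisson(config.duplicate_lambda))
        ledger_rows.append((r.sequence_id, r.isotype, n_reads))
        for k in range(n_reads):
            s1 = _seq_errors(rng, amplicon[:L], config.seq_error_rate)
            s2 = _seq_errors(rng, revcomp(amplicon)[:L], config.seq_error_rate)
            pairs.append(
                SimulatedReadPair(
                    id=f"{r.sequence_id}:D{k}",
                    seq1=s1,
                    seq2=s2,
                    qual1=tuple(_phred(rng, len(s1), config.mean_q, config.q_sd)),
                    qual2=tuple(_phred(rng, len(s2), config.mean_q, config.q_sd)),
                )
            )
    ledger = pd.DataFrame(ledger_rows, columns=["sequence_id", "isotype", "n_reads"])
    return pairs, ledger


# ---------------------------------------------------------------------------
# single-cell contigs


LIGHT_KAPPA_PROB = 0.6
SC_TRUTH_COLUMNS = [
    "truth_clonotype_id",
    "truth_window_mutations",
    "truth_window_nt",
    "truth_extra_chain",
]
AIRR_SC_COLUMNS = [
    "cell_id",
    "locus",
    "sequence",
    "junction",
    "cdr3",
    "c_call",
    "duplicate_count",
    "subset",
    "donor",
] + SC_TRUTH_COLUMNS


def _sc_chain(
    rng: np.random.Generator,
    libraries: Mapping[str, Sequence[GermlineSegment]],
    locus: str,
    junctions_seen: dict,
) -> dict:
    lib = libraries[locus]
    vs = sorted((s for s in lib if s.segment_class == "V"), key=lambda s: s.name)
    js = sorted((s for s in lib if s.segment_class == "J"), key=lambda s: s.name)
    v = vs[int(rng.integers(len(vs)))]
    j = js[int(rng.integers(len(js)))]
    junction = _make_junction(rng, v, j, junctions_seen)
    germline = v.sequence[: v.anchor] + junction + j.sequence[j.anchor + 3 :]
    return {
        "locus": locus,
        "v_name": v.name,
        "j_name": j.name,
        "junction": junction,
        "germline": germline,
        "cdr3_start": v.anchor,
    }


def emit_sc_contigs(
    config: SimulationConfig,
    libraries: Mapping[str, Sequence[GermlineSegment]],
    window_start: int = 300,
    window_end: int = 21,
) -> pd.DataFrame:
    """Emit a cell-barcoded chain table (AIRR-style TSV columns).

    Every cell carries one heavy and one light consensus chain; with
    probability ``multichain_rate`` it carries one or two extra chains.
    Cells are grouped into planted clonotypes (shared junctions) whose sizes
    follow the clone-size law.  Per-cell SHM is applied outside the junction
    at ``shm_rate`` per site, and the true mutation count within the
    ``window_start``..``window_end`` window upstream of CDR3 is recorded in
    ``truth_`` columns.
    """
    config.validate()
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    for locus in ("IGH", "IGK", "IGL"):
        if locus not in libraries:
            raise ValueError(f"libraries must include {locus}")
    rng = np.random.default_rng([abs(int(config.seed)), 3])
    junctions_seen: dict = {}

    # planted clonotypes with Zipf-ish cell multiplicities
    clonotypes: list[tuple[dict, dict]] = []
    multiplicities: list[int] = []
    total = 0
    while total < config.n_cells:
        m = int(min(rng.zipf(config.clone_size_law), 6))
        m = min(m, config.n_cells - total)
        light_locus = "IGK" if rng.random() < LIGHT_KAPPA_PROB else "IGL"
        heavy = _sc_chain(rng, libraries, "IGH", junctions_seen)
        light = _sc_chain(rng, libraries, light_locus, junctions_seen)
        clonotypes.append((heavy, light))
        multiplicities.append(m)
        total += m

    isotypes = sorted(config.isotype_probs)

    def draw_isotype(subset: str) -> str:
        table = config.isotype_probs
        if config.isotype_probs_by_subset is not None:
            table = config.isotype_probs_by_subset.get(subset, table)
        p = np.array([table.get(i, 0.0) for i in isotypes])
        return isotypes[int(rng.choice(len(isotypes), p=p / p.sum()))]

    rows = []
    cell_idx = 0
    for ct_idx, ((heavy, light), m) in enumerate(zip(clonotypes, multiplicities)):
        for _ in range(m):
            cell_id = f"cell{cell_idx:05d}"
            cell_idx += 1
            subset = "CD11c_pos" if rng.random() < config.cd11c_pos_rate else "CD11c_neg"
            chains = [(heavy, False), (light, False)]
            if rng.random() < config.multichain_rate:
                for _ in range(int(rng.integers(1, 3))):
                    locus = ("IGH", "IGK", "IGL")[int(rng.integers(3))]
                    chains.append((_sc_chain(rng, libraries, locus, junctions_seen), True))
            for chain, extra in chains:
                germ = chain["germline"]
                jn_start = chain["cdr3_start"]
                protected = range(jn_start, jn_start + len(chain["junction"]))
                mutated, muts = _mutate(rng, germ, config.shm_rate, protected)
                w_lo = max(0, jn_start - window_start)
                w_hi = max(0, jn_start - window_end + 1)
                n_window = sum(1 for p, _, _ in muts if w_lo <= p < w_hi)
                if chain["locus"] == "IGH":
                    c_call = draw_isotype(subset)
                else:
                    c_call = "IGKC" if chain["locus"] == "IGK" else "IGLC"
                dup = (
                    int(rng.poisson(3)) + 1 if extra else int(rng.poisson(30)) + 5
                )
                rows.append(
                    {
                        "cell_id": cell_id,
                        "locus": chain["locus"],
                        "sequence": mutated,
                        "junction": chain["junction"],
                        "cdr3": chain["junction"][3:-3],
                        "c_call": c_call,
                        "duplicate_count": dup,
                        "subset": subset,
                        "donor": "D1",
                        "truth_clonotype_id": f"CT{ct_idx:04d}",
                        "truth_window_mutations": n_window,
                        "truth_window_nt": w_hi - w_lo,
                        "truth_extra_chain": extra,
                    }
                )
    return pd.DataFrame(rows, columns=AIRR_SC_COLUMNS)


# ---------------------------------------------------------------------------
# accessibility counts


ATAC_CLASSES = ("null", "ctrl_diff_tbet_dep", "ctrl_diff_tbet_indep")


def simulate_atac_counts(
    seed: int,
    n_loci: int,
    class_probs: Mapping[str, float],
    effect_size: float,
    dispersion: float,
    n_reps: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial accessibility counts with planted locus classes.

    For one stimulus, counts are generated for genotypes CTL and MUT in
    unstimulated and stimulated states.  Differential classes change by
    ``effect_size``-fold on stimulation in CTL (direction random); loci of
    class ``ctrl_diff_tbet_dep`` revert to fold change 1 in MUT, while
    ``ctrl_diff_tbet_indep`` loci keep the effect in MUT.

    Returns a long count table (locus_id, genotype, stimulus, replicate,
    count) and a truth table (locus_id, true_class, direction).
    """
    if set(class_probs) - set(ATAC_CLASSES):
        raise ValueError(f"class_probs keys must be among {ATAC_CLASSES}")
    _check_probs({k: class_probs.get(k, 0.0) for k in ATAC_CLASSES}, "class_probs")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 per condition for differential testing")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    rng = np.random.default_rng([abs(int(seed)), 4])
    p = np.array([class_probs.get(k, 0.0) for k in ATAC_CLASSES])
    classes = rng.choice(len(ATAC_CLASSES), size=n_loci, p=p / p.sum())
    base_mu = rng.lognormal(mean=math.log(100.0), sigma=0.5, size=n_loci)
    up = rng.random(n_loci) < 0.5
    locus_ids = [f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(n_loci)]

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mu)
        n = 1.0 / dispersion
        return rng.negative_binomial(n, n / (n + mu))

    rows = []
    for genotype in ("CTL", "MUT"):
        for stimulus in ("unstim", "stim"):
            fc = np.ones(n_loci)
            if stimulus == "stim":
                eff = np.where(up, effect_size, 1.0 / effect_size)
                diff = classes > 0 if genotype == "CTL" else classes == 2
                fc = np.where(diff, eff, 1.0)
            for rep in range(1, n_reps + 1):
                counts = draw(base_mu * fc)
                rows.append(
                    pd.DataFrame(
                        {
                            "locus_id": locus_ids,
                            "genotype": genotype,
                            "stimulus": stimulus,
                            "replicate": rep,
                            "count": counts,
                        }
                    )
                )
    truth = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "true_class": [ATAC_CLASSES[c] for c in classes],
            "direction": np.where(classes == 0, "none", np.where(up, "up", "down")),
        }
    )
    return pd.concat(rows, ignore_index=True), truth
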