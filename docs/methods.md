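# Methods

## Scope and model

bcrflow implements a bulk and single-cell BCR repertoire analysis chain
and a chromatin-accessibility classification layer, exercised end to end
on a synthetic generator with planted ground truth. The generator is not
a fixture: it is the definition of the study conditions under which the
pipeline's guarantees (exact clone recovery, SHM recovery, count
conservation, caller calibration) are stated and tested.

## Synthetic repertoires

**Germline model.** Toy V segments are 303 nt: 300 nt of random
framework followed by a terminal cysteine anchor codon (TGT/TGC). The
300-nt framework guarantees the 280-nt SHM window (positions −300…−21
from the CDR3 start) is always fully covered. J segments are 48 nt with
the conserved anchor (TGG for IGH; TTT/TTC for IGK/IGL) at offset 9,
followed by 36 nt of FR4. Random 300-mers differ pairwise at far more
than 10 positions, so segment assignment on error-free data is
unambiguous.

**Junction model.** No explicit D segments: a junction is
V-anchor codon + N region + J 5′ region through the J anchor codon.
N-region lengths are drawn from {0, 3, …, 15} nt — multiples of 3, so
every junction is a multiple of 3 and in frame. D calls are not consumed
by any downstream statistic, so this loses nothing the pipeline measures.
Within one (V, J, junction-length) group, new junctions are
rejection-sampled until pairwise identity with previously planted
junctions is ≤ 0.85; planted clones are therefore separable at the 90%
clustering threshold and the planted partition is the unique correct
answer at low SHM.

**Clone sizes.** Zipf(a) with a = 1.5 by default, the heavy-tailed
("a few expanded clones") regime typical of IgM repertoires. When an
exact repertoire size n is requested, n − k extra members are allocated
over the k clones by a multinomial on the Zipf weights (each clone keeps
at least one member).

**SHM.** Uniform per-site substitutions at `shm_rate` per member,
independent across members; alternative bases equiprobable. Hotspot bias
(WRC/GYW), indels and lineage structure within a clone are deliberately
absent, so passing tests show correct counting and clustering arithmetic,
not robustness to realistic mutation spectra.

**Reads.** The sense-strand amplicon is the rearrangement followed by the
reverse complement of the isotype's constant-region primer; read 1 is the
first `read_length` nt of the amplicon and read 2 the first `read_length`
nt of its reverse complement, so read 2 begins with the primer exactly as
printed, and 2×300 pairs always overlap mid-amplicon (amplicon ≈ 406–421
nt). The published IgA and IgE primers are used verbatim for IGHA1 and
IGHE; the other subclasses get synthetic primers in the same 34 + 21 nt
style so each subclass is taggable by exact match. Per-base Phred scores
are truncated-normal (mean_q, q_sd) clamped to [2, 41] — only the
mean-quality filter consumes them. PCR duplicates are 1 + Poisson(λ) per
molecule, with molecule and duplicate index encoded in read ids so dedup
is verifiable exactly. Read orientation relative to V/C regions is a
declared convention, not a measured fact about any particular protocol.

**Single cells.** Cells are grouped into planted clonotypes (shared
heavy and light junctions) with Zipf-ish multiplicities capped at 6.
Every cell carries one heavy and one light consensus chain; with
probability `multichain_rate` it carries 1–2 extra chains at lower
duplicate counts. Per-cell SHM is applied outside the junction so
clonotype identity is exact by construction while the windowed mutation
frequency still equals `shm_rate`; the planted window mutation count is
recorded per chain. Subset labels (CD11c⁺/CD11c⁻) are Bernoulli, with
optional subset-specific isotype tables.

**Accessibility counts.** Negative-binomial counts (size 1/dispersion)
around lognormal baselines for CTL and MUT genotypes in unstimulated and
stimulated states. Differential classes change `effect_size`-fold on
stimulation in CTL (direction random per locus); `ctrl_diff_tbet_dep`
loci revert to fold change 1 in MUT, `ctrl_diff_tbet_indep` loci keep the
effect.

## Preprocessing

Merging scans every suffix/prefix overlap ≥ `min_overlap` (default 10)
after reverse-complementing mate 2, keeps those with mismatch fraction
≤ `max_mismatch_frac` (default 0.25), and picks the lowest mismatch
fraction, ties going to the longer overlap; within the overlap the
higher-quality base wins and the merged quality is the max. Failure to
merge is a counted outcome, not an error. The quality filter keeps
sequences whose arithmetic mean Phred is ≥ 20 (boundary inclusive) —
mean, not per-base minimum, matching the common filter default.
Primer tagging requires an exact, unambiguous match at the 3′ end of the
merged sense strand; tables must be mutually suffix-free (validated), and
`sense_primer_table` converts printed (read-2 orientation) primers to the
sense-strand form the pipeline matches. Deduplication keys on
(sequence, isotype) — clone sizes are reported per isotype — and orders
output by descending duplicate count, then lexicographically. Every stage
conserves counts: input = kept + discarded per reason, and
Σ duplicate_count equals the tagged read count.

## Annotation

Best local alignment per segment with match +5, mismatch −4, gap open −8,
gap extend −1 (Smith–Waterman via Biopython's PairwiseAligner); the J is
sought 3′ of the V alignment. Score floors (V 60, J 25) mark junk as
unassignable rather than forcing a call. Ties between segments are broken
lexicographically by name. The CDR3 uses the junction convention — from
the first base of the V cysteine codon through the last base of the J
anchor codon, both mapped through the alignment — with a `cdr3_imgt` view
stripping the anchors. CDR3 absence (anchor outside the aligned region,
or a span that is not a positive multiple of 3) is a value; QC fails
records with no CDR3 or a V alignment shorter than 100 nt ("truncated",
a declared stand-in since no canonical length cutoff exists for the toy
library). All coordinates are 0-based half-open.

## Clone inference

Partition on (V gene, J gene, CDR3 length), then greedy abundance-sorted
centroid clustering (CD-HIT style) within each partition: sequences are
processed in descending duplicate count, ties lexicographic then input
position; each joins the first centroid with Hamming identity ≥ 0.9 or
founds a new one. The total processing order makes the result independent
of input order, and every member is ≥ threshold identity to its centroid
by construction. Greedy clustering refines the single-linkage components
of the identity graph (it never joins across components) but may split a
chain A–B–C where A and C are each within threshold of B but not of one
another; the greedy answer is the defined behaviour. Heavy- and
light-chain repertoires are clustered the same way but reported
separately; allele suffixes (`*01`) are collapsed to gene level before
grouping.

## SHM quantification

Bulk percent SHM is 100 × mismatched/aligned V positions, gap columns
excluded from numerator and denominator; per-clone medians are computed
per isotype (even counts use the midpoint). The single-cell window spans
inclusive offsets −300…−21 from the CDR3 start — exactly 280 positions,
never touching the CDR3 (a 20-nt guard remains). Chains whose sequence or
alignment covers only part of the window contribute the positions
actually aligned rather than being excluded (light chains with short V
coverage would otherwise bias cell exclusion). Cell-level frequency pools
counts — Σ mutations / Σ counted nt — not the mean of per-chain rates,
and the >1% cutoff is strict (a cell at exactly 1.00% is not flagged).
Cells with zero counted positions are missing, excluded from fractions.

## Repertoire statistics

Hill numbers with q = 1 via the Shannon limit; D20 as the mass fraction
of the 20 largest clones (ties at the cut broken by clone id; < 20 clones
→ 1.0). D20 is an interpretation — "top-20 share" is the common reading
of the name. Clonotypes key on exact (heavy, light) junction or CDR3
identity after reducing each cell to its most-supported chain per locus
(max duplicate count, ties lexicographic); cells lacking either locus are
excluded from pairing. "Expanded" means ≥ 2 member cells. Cells with more
than 4 chains are counted separately as likely doublets. Subclass
frequency tables count a clone once per subclass it contains; all
frequency tables sum to 1 within 1e-9.

## Accessibility classification

The differential caller normalises by library size, tests
log2(count + 0.5) with a two-sided Welch t-test per locus, corrects with
Benjamini–Hochberg across loci, and requires adjusted p < α (default
0.05) and |log2FC| ≥ 1. It is a declared simple caller: the
classification and overlap layer also accepts externally produced call
tables, so output from a dedicated count-model tool can be plugged in
unchanged. "Unaltered in mutant" means not significant at the same α in
the mutant comparison — not an equivalence test — which is the stated
interpretation behind the T-bet-dependent class. Loci with identical
groups produce NaN t-statistics, mapped to p = 1. Percentages print as
integers rounded half-up, matching the usual reporting style.

## Problem sizes and numerical choices in the acceptance script

The script regenerates everything at: 1,000 sequences / 100 clones with
per-site SHM 2×10⁻⁵ for exact clone recovery (well inside the
low-divergence regime where the planted partition is the unique answer —
at higher rates a member can acquire two CDR3 mutations and legitimately
exceed 10% divergence from its clone); 2,000 cells at 2% SHM for window
recovery; 300 molecules with duplicate λ = 1 for conservation; 20 × 300
all-null loci (3 replicates) plus 500 loci with a 4-fold planted effect
(5 replicates, dispersion 0.05) for caller calibration. Seeds derive from
the CLI `--seed` and fully determine every output.

## Limitations

No indel SHM, hotspot targeting, insert-size variation, or sequencing
error beyond uniform substitution; no allele inference, productivity
calling, or full IMGT numbering; no lineage trees or cross-sample clone
tracking; no peak calling or motif analysis upstream/downstream of the
count tables. Results on the generator demonstrate the pipeline's
arithmetic and invariants, not performance on real repertoires with
biased mutation spectra, allelic variation, or structured sequencing
error.
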