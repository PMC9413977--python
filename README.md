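# bcrflow

Analysis of human B-cell receptor (BCR) repertoires from bulk amplicon
sequencing and single-cell VDJ data, plus the set logic used to classify
T-bet-dependent chromatin-accessibility changes in activated B cells.

The package is aimed at immunogenomics analysts who need a small, fully
testable repertoire pipeline: every stage — read preprocessing, V/J
annotation, clone inference, somatic-hypermutation (SHM) quantification,
repertoire statistics, differential-accessibility classification — runs
against a bundled synthetic-repertoire generator with planted ground
truth, so parameter recovery can be asserted rather than assumed.

## What it computes

**Clones.** Rearrangements are grouped on (V gene, J gene, CDR3 length)
and the equal-length CDR3 nucleotide sequences are clustered greedily
around abundance-sorted centroids at a 90% identity threshold, where
identity = (L − d_H)/L with d_H the Hamming distance. Each cluster is one
clone, sized as unique sequences and as total reads, with per-isotype
median SHM.

**SHM.** Bulk: 100 × (mismatched aligned V positions) / (aligned V
length), gaps excluded. Single cell: mutations relative to germline are
counted in a 280-nt window spanning positions −300 to −21 upstream of the
CDR3 start for each heavy and light chain, and pooled per cell as
Σ mutations / Σ nucleotides counted; cells with a pooled frequency
strictly above 1% are flagged as highly mutated.

**Diversity.** Hill numbers ^qD = (Σ p_i^q)^{1/(1−q)} of the clone-size
proportions (q = 0 richness, q = 1 exp of Shannon entropy, q = 2 inverse
Simpson), and D20, the fraction of repertoire mass held by the 20 largest
clones.

**Single-cell structure.** Clonotypes keyed on exact heavy+light junction
(or CDR3) identity; expanded-clonotype fraction (≥ 2 cells); fraction of
cells with 3–4 consensus chains; isotype-class frequencies per CD11c⁺ /
CD11c⁻ subset.

**Accessibility set logic.** Per-locus stimulated-vs-unstimulated calls
(library-size-normalised log2 counts, Welch t-test, Benjamini–Hochberg,
fold-change floor) in control and T-bet-deficient samples; a locus
significant in control but not in the mutant is T-bet-dependent,
significant in both is T-bet-independent. Overlaps and retained
percentages are reported as integers rounded half-up.

## Worked example

Simulate a 5-clone heavy-chain repertoire of 40 molecules, sequence it
with PCR duplicates, and run the full chain back to clones:

```python
import bcrflow as bf
from bcrflow.preprocess import ReadPair, run_preprocess
from bcrflow.pipeline import annotate_processed, infer_clones
from bcrflow.stats import hill_diversity, d20

lib = bf.build_germline_library(seed=7, n_v=4, n_j=2, chain="IGH")
cfg = bf.SimulationConfig(seed=7, n_clones=5, n_sequences=40,
                          shm_rate=0.01, duplicate_lambda=1.0)
rep = bf.simulate_repertoire(cfg, lib)
pairs, ledger = bf.emit_bulk_reads(rep, cfg)
print("read pairs:", len(pairs))

reads = [ReadPair(p.id, p.seq1, p.seq2, p.qual1, p.qual2) for p in pairs]
unique, report = run_preprocess(reads, bf.DEFAULT_PRIMERS)
print("unique sequences:", len(unique), "| merged:", report["merged"],
      "| tagged:", report["tagged"])

annotated, _ = annotate_processed(unique, lib)
clones, membership = infer_clones(annotated, threshold=0.9)
sizes = [c.size_total for c in clones]
print("clones:", len(clones), "| total reads:", sum(sizes))
print("hill q=1: %.3f | d20: %.3f" % (hill_diversity(sizes, 1), d20(sizes)))
```

Output:

```
read pairs: 74
unique sequences: 40 | merged: 74 | tagged: 74
clones: 5 | total reads: 73
hill q=1: 4.018 | d20: 1.000
```

The 74 read pairs (40 molecules plus Poisson PCR duplicates) all merge,
pass the mean-Q20 filter and are tagged by their constant-region primer;
deduplication returns exactly the 40 molecules. One molecule carries a
substitution in its V-anchor codon, so its CDR3 is unidentifiable and it
is QC-dropped — the remaining 73 reads fall into exactly the 5 planted
clones. The effective number of clones (3 large + 2 small → ⁱD ≈ 4.0) and
D20 = 1.0 (fewer than 20 clones) follow from the clone sizes.

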