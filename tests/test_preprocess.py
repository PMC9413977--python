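"""Preprocessing: merging, quality filter, primer tagging, deduplication."""

import random

import pytest
from hypothesis import given, strategies as st

import bcrflow as bf
from bcrflow.preprocess import (
    ProcessedSequence,
    ReadPair,
    TrimFailure,
    deduplicate,
    merge_pair,
    filter_quality,
    run_preprocess,
    sense_primer_table,
    trim_and_tag,
)
from bcrflow.simulate import revcomp


def _pair(seq1, seq2, q1=None, q2=None):
    q1 = q1 or (30,) * len(seq1)
    q2 = q2 or (30,) * len(seq2)
    return ReadPair(id="p", seq1=seq1, seq2=seq2, qual1=tuple(q1), qual2=tuple(q2))


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMergePair:
    def test_exact_overlap_length_arithmetic(self):
        rng = random.Random(0)
        a, b, c = _random_seq(rng, 60), _random_seq(rng, 50), _random_seq(rng, 60)
        merged = merge_pair(_pair(a + b, revcomp(b + c)))
        assert merged is not None
        assert merged.sequence == a + b + c
        assert len(merged.sequence) == len(a + b) + len(b + c) - 50

    def test_no_qualifying_overlap_returns_failure(self):
        merged = merge_pair(_pair("A" * 40, "C" * 40, ))
        # revcomp("C"*40) = "G"*40: every overlap is all mismatches
        assert merged is None

    def test_mismatched_overlap_takes_higher_quality_base(self):
        rng = random.Random(1)
        a = _random_seq(rng, 30)
        overlap1 = "ACGGTTCACGATAGCTTGCA"  # 20 nt, aperiodic
        overlap2 = "T" + overlap1[1:19] + "T"  # mismatches at positions 0 and 19
        c = _random_seq(rng, 30)
        s1 = a + overlap1
        s2_template = overlap2 + c
        q1 = [30] * len(a) + [40] + [30] * 18 + [10]
        q2_template = [20] + [30] * 18 + [35] + [30] * len(c)
        pair = _pair(s1, revcomp(s2_template), q1, q2_template[::-1])
        merged = merge_pair(pair, min_overlap=10, max_mismatch_frac=0.25)
        assert merged is not None
        assert merged.overlap == 20 and merged.mismatches == 2
        # position 0 of overlap: read 1 wins (Q40 vs Q20); position 19: read 2 (Q35 vs Q10)
        got = merged.sequence[len(a) : len(a) + 20]
        assert got[0] == overlap1[0] and got[19] == overlap2[19]

    def test_brute_force_overlap_oracle(self):
        rng = random.Random(2)
        for _ in range(20):
            amplicon = _random_seq(rng, 120)
            s1, s2t = amplicon[:80], amplicon[40:]
            pair = _pair(s1, revcomp(s2t))
            merged = merge_pair(pair, min_overlap=10, max_mismatch_frac=0.25)
            # oracle: enumerate all overlaps, pick min mismatch frac then longest
            best = None
            for o in range(10, min(len(s1), len(s2t)) + 1):
                mism = sum(x != y for x, y in zip(s1[-o:], s2t[:o]))
                frac = mism / o
                if frac <= 0.25 and (
                    best is None or frac < best[0] or (frac == best[0] and o > best[1])
                ):
                    best = (frac, o)
            assert merged is not None and best is not None
            assert merged.overlap == best[1]

    def test_mate_swap_symmetry(self):
        rng = random.Random(3)
        amplicon = _random_seq(rng, 100)
        s1, s2t = amplicon[:70], amplicon[30:]
        fwd = merge_pair(_pair(s1, revcomp(s2t)))
        swapped = merge_pair(_pair(revcomp(s2t), s1))
        assert fwd is not None and swapped is not None
        assert swapped.sequence == revcomp(fwd.sequence)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            ReadPair(id="x", seq1="ACGT", seq2="ACGT", qual1=(30,), qual2=(30,) * 4)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "quals,keep",
        [
            ((20, 20, 20, 20), True),  # boundary inclusive
            ((19, 19, 19, 19), False),
            ((10, 10, 30, 30), True),  # mean exactly 20
        ],
    )
    def test_mean_q20_boundary(self, quals, keep):
        assert filter_quality("ACGT", quals) is keep


class TestTrimAndTag:
    def test_printed_iga_primer_tagged_and_trimmed(self):
        body = "ATGCATGCATGCATGC"
        result = trim_and_tag(body + bf.IGA_PRIMER, {"IGHA1": bf.IGA_PRIMER})
        assert result == (body, "IGHA1")

    def test_single_substitution_in_primer_discards(self):
        broken = bf.IGA_PRIMER[:-1] + ("A" if bf.IGA_PRIMER[-1] != "A" else "G")
        result = trim_and_tag("ATGC" + broken, {"IGHA1": bf.IGA_PRIMER})
        assert result == TrimFailure("no-primer")

    def test_no_primer_discards(self):
        result = trim_and_tag("ATGCATGC", bf.DEFAULT_PRIMERS)
        assert result == TrimFailure("no-primer")

    def test_suffix_primers_rejected_at_validation(self):
        with pytest.raises(ValueError, match="suffix-free"):
            trim_and_tag("AAAA", {"A": "ACGT", "B": "TTACGT"})

    def test_default_table_distinguishes_all_subclasses(self):
        for iso, primer in bf.DEFAULT_PRIMERS.items():
            assert trim_and_tag("ATGC" + primer, bf.DEFAULT_PRIMERS) == ("ATGC", iso)


class TestDeduplicate:
    def test_identical_reads_collapse(self):
        recs = [("ACGT", "IGHG1", 30.0)] * 5
        out = deduplicate(recs)
        assert len(out) == 1 and out[0].duplicate_count == 5

    def test_key_includes_isotype(self):
        out = deduplicate([("ACGT", "IGHG1", 30.0), ("ACGT", "IGHA1", 30.0)])
        assert len(out) == 2

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGT", min_size=1, max_size=6),
                st.sampled_from(["IGHM", "IGHG1"]),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_conserving(self, items):
        recs = [(s, i, 30.0) for s, i in items]
        once = deduplicate(recs)
        assert sum(r.duplicate_count for r in once) == len(recs)
        assert {(r.sequence, r.isotype) for r in once} == set(items)
        twice = deduplicate([(r.sequence, r.isotype, r.mean_q) for r in once])
        assert [(r.sequence, r.isotype) for r in twice] == sorted(set(items))
        assert all(r.duplicate_count == 1 for r in twice)


class TestEndToEnd:
    def test_round_trip_conservation_and_duplicate_recovery(self, igh_library):
        cfg = bf.SimulationConfig(
            seed=21, n_clones=8, n_sequences=40, shm_rate=0.01, duplicate_lambda=1.5
        )
        rep = bf.simulate_repertoire(cfg, igh_library)
        pairs, ledger = bf.emit_bulk_reads(rep, cfg)
        read_pairs = [ReadPair(p.id, p.seq1, p.seq2, p.qual1, p.qual2) for p in pairs]
        unique, report = run_preprocess(read_pairs, bf.DEFAULT_PRIMERS)
        assert report["input_pairs"] == report["merged"] + report["merge_failed"]
        assert report["merged"] == (
            report["quality_passed"] + report["quality_failed"]
        )
        assert report["duplicate_count_total"] == report["tagged"]
        # zero sequencing error: every molecule recovered with its ledger count
        truth = {(r.full_sequence, r.isotype) for r in rep}
        got = {(u.sequence, u.isotype) for u in unique}
        assert got == truth
        counts: dict = {}
        for r, n in zip(rep, ledger["n_reads"]):
            key = (r.full_sequence, r.isotype)
            counts[key] = counts.get(key, 0) + int(n)
        for u in unique:
            assert u.duplicate_count == counts[(u.sequence, u.isotype)]

    def test_sense_table_is_revcomp(self):
        table = sense_primer_table({"IGHA1": bf.IGA_PRIMER})
        assert table["IGHA1"] == revcomp(bf.IGA_PRIMER)
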