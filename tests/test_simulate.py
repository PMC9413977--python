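"""Generator contracts: determinism, anchors, conservation, planted rates."""

import numpy as np
import pytest

import bcrflow as bf
from bcrflow.simulate import J_PRE_ANCHOR, V_UPSTREAM


class TestGermlineLibrary:
    def test_composition_and_anchors(self):
        lib = bf.build_germline_library(1, 3, 2, "IGH")
        vs = [s for s in lib if s.segment_class == "V"]
        js = [s for s in lib if s.segment_class == "J"]
        assert len(vs) == 3 and len(js) == 2
        assert len({s.name for s in lib}) == 5
        for v in vs:
            assert v.anchor == V_UPSTREAM
            assert v.sequence[v.anchor : v.anchor + 3] in ("TGT", "TGC")
            assert len(v.sequence) - v.anchor == 3  # V ends with the Cys codon
        for j in js:
            assert j.sequence[j.anchor : j.anchor + 3] == "TGG"

    def test_light_chain_j_anchor_is_phe(self):
        for chain in ("IGK", "IGL"):
            js = [
                s
                for s in bf.build_germline_library(1, 1, 3, chain)
                if s.segment_class == "J"
            ]
            for j in js:
                assert j.sequence[J_PRE_ANCHOR : J_PRE_ANCHOR + 3] in ("TTT", "TTC")

    def test_deterministic_and_seed_sensitive(self):
        a = bf.build_germline_library(1, 3, 2, "IGH")
        b = bf.build_germline_library(1, 3, 2, "IGH")
        c = bf.build_germline_library(2, 3, 2, "IGH")
        assert a == b
        assert any(x.sequence != y.sequence for x, y in zip(a, c))

    def test_invalid_chain_names_allowed_set(self):
        with pytest.raises(ValueError, match="IGH, IGK, IGL"):
            bf.build_germline_library(1, 1, 1, "TRB")


class TestRepertoire:
    def test_zero_shm_members_equal_germline(self, small_repertoire):
        _, rep = small_repertoire
        for r in rep:
            assert r.mutated_positions == ()
            assert r.full_sequence == r.germline_sequence
            assert r.junction_nt in r.full_sequence

    def test_single_clone_degenerate(self, igh_library):
        cfg = bf.SimulationConfig(seed=3, n_clones=1, n_sequences=15)
        rep = bf.simulate_repertoire(cfg, igh_library)
        assert len({r.clone_id for r in rep}) == 1

    def test_size_conservation_exact_total(self, igh_library):
        cfg = bf.SimulationConfig(seed=4, n_clones=10, n_sequences=57)
        rep = bf.simulate_repertoire(cfg, igh_library)
        assert len(rep) == 57
        assert len({r.clone_id for r in rep}) == 10

    def test_shm_rate_recovered_binomially(self, igh_library):
        rate = 0.02
        cfg = bf.SimulationConfig(seed=6, n_clones=5, n_sequences=40, shm_rate=rate)
        rep = bf.simulate_repertoire(cfg, igh_library)
        sites = sum(len(r.full_sequence) for r in rep)
        muts = sum(len(r.mutated_positions) for r in rep)
        se = np.sqrt(rate * (1 - rate) / sites)
        assert abs(muts / sites - rate) < 3 * se

    def test_mutated_positions_consistent(self, igh_library):
        cfg = bf.SimulationConfig(seed=7, n_clones=5, n_sequences=30, shm_rate=0.05)
        rep = bf.simulate_repertoire(cfg, igh_library)
        for r in rep:
            for pos, ref, alt in r.mutated_positions:
                assert r.full_sequence[pos] == alt
                assert r.germline_sequence[pos] == ref
                assert ref != alt

    def test_unnormalised_isotype_probs_rejected(self, igh_library):
        cfg = bf.SimulationConfig(seed=1, isotype_probs={"IGHM": 0.5, "IGHG1": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            bf.simulate_repertoire(cfg, igh_library)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="at least one V"):
            bf.simulate_repertoire(bf.SimulationConfig(seed=1), [])


class TestBulkReads:
    def test_single_iga_molecule_read2_carries_printed_primer(self, igh_library):
        cfg = bf.SimulationConfig(
            seed=8,
            n_clones=1,
            n_sequences=1,
            duplicate_lambda=0.0,
            isotype_probs={"IGHA1": 1.0},
        )
        rep = bf.simulate_repertoire(cfg, igh_library)
        pairs, ledger = bf.emit_bulk_reads(rep, cfg)
        assert len(pairs) == 1
        assert pairs[0].seq2.startswith(bf.IGA_PRIMER)
        assert len(bf.IGA_PRIMER) == 55
        assert ledger["n_reads"].tolist() == [1]

    def test_duplicate_ledger_matches_emitted_pairs(self, igh_library):
        cfg = bf.SimulationConfig(seed=9, n_clones=5, n_sequences=30, duplicate_lambda=2.0)
        rep = bf.simulate_repertoire(cfg, igh_library)
        pairs, ledger = bf.emit_bulk_reads(rep, cfg)
        assert ledger["n_reads"].sum() == len(pairs)
        assert len(pairs) > len(rep)
        # read ids encode molecule and duplicate index
        assert pairs[0].id == f"{rep[0].sequence_id}:D0"

    def test_missing_primer_errors_name_isotypes(self, igh_library):
        cfg = bf.SimulationConfig(seed=8, n_clones=1, n_sequences=1,
                                  isotype_probs={"IGHA1": 1.0})
        rep = bf.simulate_repertoire(cfg, igh_library)
        with pytest.raises(ValueError, match="IGHA1"):
            bf.emit_bulk_reads(rep, cfg, primers={"IGHM": "ACGT"})

    def test_byte_identical_on_rerun(self, igh_library):
        cfg = bf.SimulationConfig(seed=10, n_clones=3, n_sequences=10)
        rep = bf.simulate_repertoire(cfg, igh_library)
        p1, _ = bf.emit_bulk_reads(rep, cfg)
        p2, _ = bf.emit_bulk_reads(rep, cfg)
        assert p1 == p2


class TestScContigs:
    def test_multichain_rate_extremes(self, sc_libraries):
        cfg0 = bf.SimulationConfig(seed=12, n_cells=40, multichain_rate=0.0)
        chains = bf.emit_sc_contigs(cfg0, sc_libraries).groupby("cell_id").size()
        assert (chains == 2).all()
        cfg1 = bf.SimulationConfig(seed=12, n_cells=40, multichain_rate=1.0)
        chains = bf.emit_sc_contigs(cfg1, sc_libraries).groupby("cell_id").size()
        assert chains.isin([3, 4]).all()

    def test_every_cell_paired(self, sc_libraries):
        cfg = bf.SimulationConfig(seed=13, n_cells=60, multichain_rate=0.2)
        df = bf.emit_sc_contigs(cfg, sc_libraries)
        for _, sub in df.groupby("cell_id"):
            assert (sub["locus"] == "IGH").any()
            assert sub["locus"].isin(["IGK", "IGL"]).any()

    def test_multichain_fraction_binomial(self, sc_libraries):
        rate = 0.05
        cfg = bf.SimulationConfig(seed=14, n_cells=2000, multichain_rate=rate)
        df = bf.emit_sc_contigs(cfg, sc_libraries)
        frac = (df.groupby("cell_id").size().isin([3, 4])).mean()
        se = np.sqrt(rate * (1 - rate) / 2000)
        assert abs(frac - rate) < 3 * se


class TestAtacCounts:
    PROBS = {"null": 0.5, "ctrl_diff_tbet_dep": 0.3, "ctrl_diff_tbet_indep": 0.2}

    def test_deterministic(self):
        a = bf.simulate_atac_counts(1, 50, self.PROBS, 4.0, 0.05, 3)
        b = bf.simulate_atac_counts(1, 50, self.PROBS, 4.0, 0.05, 3)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_effect_size_one_behaves_null(self):
        counts, _ = bf.simulate_atac_counts(2, 400, self.PROBS, 1.0, 0.05, 5)
        sub = counts[counts.genotype == "CTL"].rename(columns={"stimulus": "group"})
        calls = bf.differential_call(sub)
        assert calls["significant"].mean() < 0.02

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError, match="n_reps"):
            bf.simulate_atac_counts(1, 10, self.PROBS, 4.0, 0.05, 1)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class_probs"):
            bf.simulate_atac_counts(1, 10, {"weird": 1.0}, 4.0, 0.05, 3)
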