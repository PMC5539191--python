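"""Stage orchestration: mapping, stages 2-5, and the full pipeline."""

import numpy as np
import pytest

from plastokmer import (
    Assembly,
    ReadSet,
    ReadSimParams,
    circular_identity,
    extract_gap_contexts,
    map_reads,
    plastome_variants,
    revcomp,
    run_pipeline,
    run_stage2,
    run_stage3,
    run_stage4,
    run_stage5,
    simulate_reads,
)
from plastokmer.dna import random_seq
from plastokmer.io_formats import ReadRecord


class TestMapReads:
    @pytest.fixture()
    def asm(self):
        rng = np.random.default_rng(17)
        return Assembly.from_sequences([random_seq(3000, rng), random_seq(2000, rng)])

    def test_verbatim_read_maps_at_source(self, asm):
        seq = asm.scaffolds[0].sequence
        reads = ReadSet(singles=[ReadRecord("r", seq[700:800])])
        aln = map_reads(reads, asm)["r"]
        assert (aln.scaffold, aln.start, aln.strand) == (0, 700, "+")
        assert aln.matches == 100

    def test_reverse_complement_maps_opposite_strand(self, asm):
        seq = asm.scaffolds[1].sequence
        reads = ReadSet(singles=[ReadRecord("r", revcomp(seq[500:600]))])
        aln = map_reads(reads, asm)["r"]
        assert (aln.scaffold, aln.start, aln.strand) == (1, 500, "-")
        assert aln.matches == 100

    def test_overhang_at_scaffold_end(self, asm):
        seq = asm.scaffolds[0].sequence
        rng = np.random.default_rng(18)
        read = seq[-50:] + random_seq(50, rng)  # half the read hangs off the end
        aln = map_reads(ReadSet(singles=[ReadRecord("r", read)]), asm)["r"]
        assert aln.scaffold == 0
        assert aln.right_overhang == 50

    def test_unmappable_read_absent(self, asm):
        rng = np.random.default_rng(19)
        alns = map_reads(ReadSet(singles=[ReadRecord("r", random_seq(100, rng))]), asm)
        assert "r" not in alns


class TestExtractGapContexts:
    def test_mid_scaffold_gap_full_flanks(self):
        rng = np.random.default_rng(20)
        seq = random_seq(2000, rng) + "N" * 100 + random_seq(2000, rng)
        ctxs = extract_gap_contexts(Assembly.from_sequences([seq]), flank=500)
        assert len(ctxs) == 1
        ctx = ctxs[0]
        assert len(ctx.left_flank) == len(ctx.right_flank) == 500
        assert ctx.gap_interval == (2000, 2100)
        assert "N" not in ctx.left_flank + ctx.right_flank

    def test_flank_truncated_at_scaffold_start(self):
        rng = np.random.default_rng(21)
        seq = random_seq(50, rng) + "N" * 20 + random_seq(1000, rng)
        ctx = extract_gap_contexts(Assembly.from_sequences([seq]), flank=500)[0]
        assert len(ctx.left_flank) == 50

    def test_adjacent_gaps_split_flanks(self):
        rng = np.random.default_rng(22)
        seq = (random_seq(600, rng) + "N" * 10 + random_seq(200, rng)
               + "N" * 10 + random_seq(600, rng))
        ctxs = extract_gap_contexts(Assembly.from_sequences([seq]), flank=500)
        assert len(ctxs) == 2
        assert len(ctxs[0].right_flank) == 200
        assert len(ctxs[1].left_flank) == 200

    def test_gap_free_assembly(self):
        asm = Assembly.from_sequences(["ACGT" * 100])
        assert extract_gap_contexts(asm, 500) == []


class TestStage2:
    def test_plastome_only_gives_clean_assembly(self, truth, cfg, plastome_reads):
        best = run_stage2(plastome_reads, band=(10, 400), config=cfg)
        assert best.n_gaps == 0
        assert abs(best.total_length - 29_000) / 29_000 < 0.01  # IR collapsed once

    def test_empty_band_errors(self, cfg, plastome_reads, mixture_table):
        with pytest.raises(RuntimeError, match="band"):
            run_stage2(plastome_reads, band=(10 ** 6, 10 ** 6 + 1), config=cfg,
                       table=mixture_table)


class TestStage3:
    def test_circular_seed_terminates_immediately(self, truth, cfg, plastome_reads):
        seed = Assembly.from_sequences([truth.circle], circular=True)
        st = run_stage3(plastome_reads, seed, cfg)
        assert st.terminated_because == "circular"
        assert st.best is seed or st.best.circular

    def test_contaminated_seed_is_cleaned(self, truth, cfg, plastome_reads):
        """Nuclear-contamination scaffolds in the seed do not survive
        re-selection and re-assembly."""
        rng = np.random.default_rng(23)
        contamination = random_seq(1500, rng)
        seed = Assembly.from_sequences([truth.circle[:15000],
                                        truth.circle[15000:], contamination])
        st = run_stage3(plastome_reads, seed, cfg)
        assert st.best.circular
        main, variants = plastome_variants(truth.lsc, truth.ir, truth.ssc)
        assert circular_identity(st.best.scaffolds[0].sequence, main, variants) >= 99.9

    def test_iteration_limit_respected(self, truth, cfg, plastome_reads):
        limited = cfg.replace(max_iterations=1)
        seed = Assembly.from_sequences([truth.circle[:9000], truth.circle[12000:20000]])
        st = run_stage3(plastome_reads, seed, limited)
        assert st.iteration <= 1


class TestStage4:
    def test_restores_split_circle(self, truth, cfg, mixture_reads):
        """Two scaffolds with 300 bp deleted between them are reconnected
        into one circular assembly matching the truth."""
        c = truth.circle
        asm = Assembly.from_sequences([c[:15000], c[15300:]])
        st = run_stage4(mixture_reads, asm, cfg)
        assert st.best.circular
        assert st.terminated_because == "circular"
        main, variants = plastome_variants(truth.lsc, truth.ir, truth.ssc)
        assert circular_identity(st.best.scaffolds[0].sequence, main, variants) >= 99.9

    def test_circular_input_skipped(self, truth, cfg, plastome_reads):
        asm = Assembly.from_sequences([truth.circle], circular=True)
        st = run_stage4(plastome_reads, asm, cfg)
        assert st.terminated_because == "circular"
        assert st.best is asm

    def test_unbridgeable_break_terminates_without_improvement(self, truth, cfg):
        """With a coverage hole wider than the insert size across the break,
        no spanning evidence exists and the scaffold count is unchanged."""
        c = truth.circle
        hole = (14800, 16400)
        reads = simulate_reads(truth, None, ReadSimParams(seed=31, coverage_hole=hole))
        asm = Assembly.from_sequences([c[5000:14800], c[16400:25000]])
        st = run_stage4(reads, asm, cfg)
        assert st.best.n_scaffolds == 2
        assert st.terminated_because == "no_improvement"


class TestStage5:
    def test_closes_punched_gap_exactly(self, truth, cfg, mixture_reads):
        c = truth.circle
        punched = c[:10000] + "N" * 200 + c[10200:]
        st = run_stage5(mixture_reads, Assembly.from_sequences([punched]), cfg)
        assert st.terminated_because == "all_gaps_closed"
        assert st.best.scaffolds[0].sequence == c

    def test_never_touches_bases_outside_contexts(self, truth, cfg, mixture_reads):
        c = truth.circle
        punched = c[:10000] + "N" * 200 + c[10200:]
        st = run_stage5(mixture_reads, Assembly.from_sequences([punched]), cfg)
        out = st.best.scaffolds[0].sequence
        flank = cfg.gap_flank
        assert out[:10000 - flank] == punched[:10000 - flank]
        tail = len(punched) - (10200 + flank)
        assert out[-tail:] == punched[-tail:]

    def test_zero_coverage_gap_persists(self, truth, cfg):
        hole = (12000, 13500)
        reads = simulate_reads(truth, None, ReadSimParams(seed=7, coverage_hole=hole))
        gapped = truth.circle[:12000] + "N" * 1500 + truth.circle[13500:]
        st = run_stage5(reads, Assembly.from_sequences([gapped]), cfg)
        assert st.best.n_gaps == 1
        assert st.terminated_because == "no_improvement"

    def test_gap_free_input_unchanged(self, truth, cfg, plastome_reads):
        asm = Assembly.from_sequences([truth.circle])
        st = run_stage5(plastome_reads, asm, cfg)
        assert st.terminated_because == "all_gaps_closed"
        assert st.best is asm


class TestRunPipeline:
    def test_stop_after_stage1(self, cfg, mixture_reads):
        res = run_pipeline(mixture_reads, cfg, stop_after=1)
        assert res.final is None and res.histogram.rows

    def test_halts_without_band_when_auto_disabled(self, cfg, mixture_reads):
        res = run_pipeline(mixture_reads, cfg, auto_band=False)
        assert res.final is None

    def test_end_to_end_persists_artifacts(self, truth, cfg, mixture_reads, tmp_path):
        res = run_pipeline(mixture_reads, cfg, outdir=tmp_path)
        assert res.final.circular
        main, variants = plastome_variants(truth.lsc, truth.ir, truth.ssc)
        assert circular_identity(res.final.scaffolds[0].sequence, main, variants) >= 99.9
        for name in ("stage1_hist_bin25.tsv", "stage2_sweep.tsv", "stage2_best.fasta",
                     "run_manifest.json", "final_layout.fasta"):
            assert (tmp_path / name).exists(), name
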