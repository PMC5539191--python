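"""Orchestration of the five pipeline stages.

Stage 1 counts canonical k-mers and builds volume histograms; stage 2
selects reads whose k-mers fall in the chloroplast frequency band and runs
the K x batch assembly sweep; stage 3 iteratively re-selects reads against
the current best assembly and re-assembles; stage 4 extends and reconnects
scaffold ends with overhanging reads and spanning read pairs; stage 5 fills
remaining gaps with positively/negatively k-mer-filtered read subsets.

The read mapper used by stages 4 and 5 is an exact-k-mer-seeded, ungapped
aligner; an external SAM-producing aligner can be substituted upstream as
long as it yields per-read placements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembler import (
    Assembly,
    Provenance,
    Scaffold,
    debruijn_assemble,
    filter_homology,
    filter_size,
    rank_assemblies,
    ranking_key,
    sanity_check,
    sweep_assemble,
)
from .dna import revcomp
from .enrichment import batch_subsample, detect_peaks, select_reads
from .io_formats import (
    PipelineConfig,
    ReadRecord,
    ReadSet,
    scan_input_directory,
    write_fasta,
    write_histogram,
    write_kmer_table,
)
from .kmer_core import (
    KmerHistogram,
    KmerTable,
    count_kmers,
    histogram,
    select_kmers_by_frequency,
    table_difference,
)
from .scaffolder import ConnectivityMatrix, layout_outputs, overlap_merge, rescaffold_with_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage bookkeeping


@dataclass
class StageState:
    stage: int
    best: Assembly
    iteration: int = 0
    history: list[tuple[int, int, int, int]] = field(default_factory=list)
    terminated_because: str = "no_improvement"

    def record(self, iteration: int, asm: Assembly) -> None:
        self.history.append((iteration, asm.n_scaffolds, asm.n_gaps, asm.total_length))


@dataclass
class GapContext:
    gap_id: str
    left_flank: str
    right_flank: str
    scaffold_index: int
    gap_interval: tuple[int, int]  # (start, end) of the N-run, half-open
    flank_interval: tuple[int, int]  # context incl. flanks, half-open


# ---------------------------------------------------------------------------
# read mapping


@dataclass
class Alignment:
    read_id: str
    scaffold: int
    strand: str  # "+" | "-"
    start: int   # scaffold coordinate of the read's first base (may be < 0)
    matches: int
    left_overhang: int = 0
    right_overhang: int = 0


def _mismatches(a: str, b: str) -> int:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((x != y).sum())


def map_reads(reads: ReadSet, assembly: Assembly, seed_len: int = 31,
              n_seeds: int = 4) -> dict[str, Alignment]:
    """Place each read at the position (either strand) maximizing matches.

    Exact canonical-k-mer seeds anchor candidate placements; the best-voted
    candidate is verified by ungapped comparison with overhangs clipped at
    scaffold ends.  Reads with no seed hit are unmapped (absent from the
    result).  Deterministic.
    """
    if not assembly.scaffolds:
        return {}
    k = seed_len
    index: dict[str, list[tuple[int, int, bool]]] = {}
    for si, scaf in enumerate(assembly.scaffolds):
        seq = scaf.sequence
        for p in range(len(seq) - k + 1):
            w = seq[p:p + k]
            mid = w[k // 2]
            if mid in "AC":
                index.setdefault(w, []).append((si, p, True))
            elif mid in "GT":
                index.setdefault(revcomp(w), []).append((si, p, False))
    out: dict[str, Alignment] = {}
    for record in reads.iter_records():
        aln = _map_one(record, assembly, index, k, n_seeds)
        if aln is not None:
            out[record.id] = aln
    return out


def _seed_offsets(n_windows: int, n_seeds: int, _cache: dict = {}) -> tuple[int, ...]:
    key = (n_windows, n_seeds)
    if key not in _cache:
        _cache[key] = tuple(sorted({
            round(i * (n_windows - 1) / max(1, n_seeds - 1)) for i in range(n_seeds)
        }))
    return _cache[key]


def _map_one(record: ReadRecord, assembly: Assembly, index, k: int,
             n_seeds: int) -> Alignment | None:
    seq = record.sequence
    if len(seq) < k:
        return None
    h = k // 2
    votes: dict[tuple[int, int, str], int] = {}
    for off in _seed_offsets(len(seq) - k + 1, n_seeds):
        w = seq[off:off + k]
        mid = w[h]
        if mid in "AC":
            cw, read_fwd = w, True
        elif mid in "GT":
            cw, read_fwd = revcomp(w), False
        else:
            continue
        for si, pos, scaf_fwd in index.get(cw, ()):
            if scaf_fwd == read_fwd:
                cand = (si, pos - off, "+")
            else:
                cand = (si, pos - (len(seq) - k - off), "-")
            votes[cand] = votes.get(cand, 0) + 1
    if not votes:
        return None
    best = None
    for (si, start, strand), v in sorted(votes.items()):
        scaf = assembly.scaffolds[si].sequence
        query = seq if strand == "+" else revcomp(seq)
        lo = max(0, start)
        hi = min(len(scaf), start + len(seq))
        if hi <= lo:
            continue
        mism = _mismatches(query[lo - start:hi - start], scaf[lo:hi])
        matches = (hi - lo) - mism
        key = (-matches, si, start, strand)
        if best is None or key < best[0]:
            best = (key, Alignment(record.id, si, strand, start, matches,
                                   left_overhang=max(0, -start),
                                   right_overhang=max(0, start + len(seq) - len(scaf))))
    return best[1] if best else None


def alignments_from_sam(path: Path | str, assembly: Assembly) -> dict[str, Alignment]:
    """Adapter: per-read placements from an external aligner's SAM output.

    Satisfies the same contract as :func:`map_reads` (best placement per
    read id, clipped overhangs at scaffold ends), so BWA-style alignments
    can stand in for the internal mapper in stages 4 and 5.
    """
    import pysam

    names = {s.id: i for i, s in enumerate(assembly.scaffolds)}
    out: dict[str, Alignment] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in names:
                continue
            si = names[rec.reference_name]
            cig = rec.cigartuples or []
            left_clip = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            right_clip = cig[-1][1] if len(cig) > 1 and cig[-1][0] in (4, 5) else 0
            start = rec.reference_start - left_clip
            scaf_len = len(assembly.scaffolds[si])
            length = rec.query_length + (cig[0][1] if cig and cig[0][0] == 5 else 0) \
                + (cig[-1][1] if len(cig) > 1 and cig[-1][0] == 5 else 0)
            aln = Alignment(
                rec.query_name, si, "-" if rec.is_reverse else "+", start,
                matches=sum(n for op, n in cig if op in (0, 7)),
                left_overhang=max(0, -start),
                right_overhang=max(0, start + length - scaf_len),
            )
            prev = out.get(rec.query_name)
            if prev is None or aln.matches > prev.matches:
                out[rec.query_name] = aln
    return out


# ---------------------------------------------------------------------------
# stage 2


def _assemble_fn(config: PipelineConfig):
    def fn(batch: ReadSet, K: int) -> Assembly:
        return debruijn_assemble(
            batch, K,
            min_edge_coverage=config.min_edge_coverage,
            min_links=config.min_links,
            gap_n=config.gap_n,
        )
    return fn


def _sweep_and_filter(reads: ReadSet, config: PipelineConfig,
                      reference: list[str] | None,
                      stage: int, iteration: int = 0,
                      batch_start: int | None = None,
                      batch_increment: int | None = None,
                      ) -> tuple[list[Assembly], pd.DataFrame]:
    start = batch_start or config.batch_start
    inc = batch_increment or config.batch_increment
    batches = batch_subsample(reads, start, inc, config.seed)
    assemblies = sweep_assemble(batches, config.K_values, _assemble_fn(config))
    rows = []
    survivors: list[Assembly] = []
    for asm in assemblies:
        asm.provenance = Provenance(asm.provenance.K, asm.provenance.batch_size,
                                    stage, iteration)
        filtered = filter_size(
            filter_homology(asm, reference, config.min_homology, config.k_count),
            asm.provenance.K,
        )
        filtered.provenance = asm.provenance
        passed = sanity_check(filtered, config.size_total)
        rows.append(dict(
            K=asm.provenance.K, batch=asm.provenance.batch_size,
            n_scaffolds=filtered.n_scaffolds, n_gaps=filtered.n_gaps,
            total_length=filtered.total_length, passed_sanity=passed,
        ))
        if passed and filtered.n_scaffolds:
            survivors.append(filtered)
    return survivors, pd.DataFrame(rows)


def run_stage2(reads: ReadSet, band: tuple[int, int], config: PipelineConfig,
               reference: list[str] | None = None,
               table: KmerTable | None = None,
               outdir: Path | str | None = None) -> Assembly:
    """Band selection of k-mers and reads, K x batch sweep, filter, rank."""
    if table is None:
        table = count_kmers(reads, config.k_count)
    band_table = select_kmers_by_frequency(table, band[0], band[1])
    if len(band_table) == 0:
        raise RuntimeError(
            f"no k-mers in frequency band {band}; revise the band boundaries"
        )
    selected = select_reads(reads, band_table, config.pair_policy)
    if selected.n_reads == 0:
        raise RuntimeError(f"no reads selected by band {band}; revise the band")
    survivors, stats = _sweep_and_filter(selected, config, reference, stage=2)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stats.to_csv(outdir / "stage2_sweep.tsv", sep="\t", index=False)
    if not survivors:
        raise RuntimeError(
            "no assembly survived filtering in stage 2; revise the frequency "
            "band or the sanity length ranges"
        )
    best = rank_assemblies(survivors, config.ranking_mode)
    logger.info("stage 2 best: %d scaffolds, %d gaps, %d bp",
                best.n_scaffolds, best.n_gaps, best.total_length)
    return best


# ---------------------------------------------------------------------------
# stage 3


def run_stage3(reads: ReadSet, seed_assembly: Assembly, config: PipelineConfig,
               reference: list[str] | None = None,
               from_previous: bool = False) -> StageState:
    """Iterative re-selection of reads against the current best assembly.

    By default each iteration re-selects from the full raw dataset;
    ``from_previous`` narrows every iteration to the previously selected
    subset instead (progressively shrinking the pool).
    """
    current = overlap_merge(seed_assembly, config.min_overlap, config.max_mismatch_rate)
    if ranking_key(seed_assembly, config.ranking_mode) < ranking_key(current, config.ranking_mode):
        current = seed_assembly
    state = StageState(stage=3, best=current)
    state.record(0, current)
    if current.circular:
        state.terminated_because = "circular"
        return state
    pool = reads
    for it in range(1, config.max_iterations + 1):
        state.iteration = it
        asm_table = count_kmers(current.sequences(), config.k_count)
        selected = select_reads(pool, asm_table, config.pair_policy)
        if from_previous:
            pool = selected
        if selected.n_reads == 0:
            state.terminated_because = "no_improvement"
            return state
        survivors, _ = _sweep_and_filter(selected, config, reference, stage=3, iteration=it)
        merged = [overlap_merge(a, config.min_overlap, config.max_mismatch_rate)
                  for a in survivors]
        merged = [m for m in merged if sanity_check(m, config.size_total) and m.n_scaffolds]
        if not merged:
            state.terminated_because = "no_improvement"
            return state
        candidate = rank_assemblies(merged, config.ranking_mode)
        if ranking_key(candidate, config.ranking_mode)[:3] < ranking_key(current, config.ranking_mode)[:3]:
            current = candidate
            state.best = current
            state.record(it, current)
            if current.circular:
                state.terminated_because = "circular"
                return state
        else:
            state.terminated_because = "no_improvement"
            return state
    state.terminated_because = "iteration_limit"
    return state


# ---------------------------------------------------------------------------
# stage 4


def _collect_end_sets(reads: ReadSet, assembly: Assembly,
                      alignments: dict[str, Alignment],
                      end_window: int, min_overhang: int = 10
                      ) -> dict[tuple[int, str], list[ReadRecord]]:
    """Reads overhanging each scaffold end, plus mates of end-anchored reads."""
    mate_of: dict[str, ReadRecord] = {}
    for m1, m2 in reads.pairs:
        mate_of[m1.id] = m2
        mate_of[m2.id] = m1
    sets: dict[tuple[int, str], dict[str, ReadRecord]] = {}

    def _add(end: tuple[int, str], rec: ReadRecord) -> None:
        sets.setdefault(end, {})[rec.id] = rec

    by_id = {r.id: r for r in reads.iter_records()}
    for rid, aln in alignments.items():
        rec = by_id[rid]
        scaf_len = len(assembly.scaffolds[aln.scaffold])
        if aln.left_overhang >= min_overhang:
            _add((aln.scaffold, "L"), rec)
        if aln.right_overhang >= min_overhang:
            _add((aln.scaffold, "R"), rec)
        mate = mate_of.get(rid)
        if mate is None:
            continue
        # a '+' read near the right end (or '-' near the left) points outward;
        # its mate belongs to that end's set
        if aln.strand == "+" and scaf_len - (aln.start + len(rec)) <= end_window:
            _add((aln.scaffold, "R"), mate)
            _add((aln.scaffold, "R"), rec)
        if aln.strand == "-" and aln.start <= end_window:
            _add((aln.scaffold, "L"), mate)
            _add((aln.scaffold, "L"), rec)
    return {end: sorted(d.values(), key=lambda r: r.id) for end, d in sets.items()}


def _connectivity(reads: ReadSet, assembly: Assembly,
                  alignments: dict[str, Alignment], end_window: int) -> ConnectivityMatrix:
    matrix = ConnectivityMatrix()
    for m1, m2 in reads.pairs:
        a1, a2 = alignments.get(m1.id), alignments.get(m2.id)
        if a1 is None or a2 is None or a1.scaffold == a2.scaffold:
            continue
        ends = []
        for aln, rec in ((a1, m1), (a2, m2)):
            scaf_len = len(assembly.scaffolds[aln.scaffold])
            if aln.strand == "+" and scaf_len - (aln.start + len(rec)) <= end_window:
                ends.append((aln.scaffold, "R"))
            elif aln.strand == "-" and aln.start <= end_window:
                ends.append((aln.scaffold, "L"))
        if len(ends) == 2:
            matrix.add(ends[0], ends[1])
    return matrix


def run_stage4(reads: ReadSet, assembly: Assembly, config: PipelineConfig,
               reference: list[str] | None = None) -> StageState:
    """Scaffold extension and spanning-read re-scaffolding.

    Skipped when the input is already circular.
    """
    state = StageState(stage=4, best=assembly)
    state.record(0, assembly)
    if assembly.circular:
        state.terminated_because = "circular"
        return state
    current = assembly
    seed_len = min(config.k_count, 31)
    for it in range(1, config.max_iterations + 1):
        state.iteration = it
        alns = map_reads(reads, current, seed_len=seed_len)
        end_sets = _collect_end_sets(reads, current, alns, config.end_window)
        new_scaffolds: list[Scaffold] = []
        for end in sorted(end_sets):
            recs = end_sets[end]
            if len(recs) < config.min_links:
                continue
            sub = ReadSet(singles=recs)
            for K in config.K_values:
                asm = debruijn_assemble(sub, K, config.min_edge_coverage,
                                        scaffold_pairs=False)
                for s in filter_size(asm, K).scaffolds:
                    new_scaffolds.append(s)
        combined = Assembly(
            current.scaffolds + [Scaffold(f"e{i}", s.sequence, s.mean_coverage)
                                 for i, s in enumerate(new_scaffolds)],
            provenance=Provenance(stage=4, iteration=it),
        )
        merged = overlap_merge(combined, config.min_overlap, config.max_mismatch_rate)
        merged = filter_homology(merged, reference, config.min_homology, config.k_count)
        if ranking_key(merged, config.ranking_mode)[:3] < ranking_key(current, config.ranking_mode)[:3]:
            current = merged
            state.best = current
            state.record(it, current)
            if current.circular:
                state.terminated_because = "circular"
                return state
        else:
            state.terminated_because = "no_improvement"
            break
    else:
        state.terminated_because = "iteration_limit"
    if not current.circular and current.n_scaffolds > 1:
        alns = map_reads(reads, current, seed_len=seed_len)
        matrix = _connectivity(reads, current, alns, config.end_window)
        bridged = rescaffold_with_matrix(current, matrix, config.min_links, config.gap_n)
        if ranking_key(bridged, config.ranking_mode)[:3] <= ranking_key(current, config.ranking_mode)[:3]:
            current = bridged
            state.best = current
            state.record(state.iteration, current)
            if current.circular:
                state.terminated_because = "circular"
    return state


# ---------------------------------------------------------------------------
# stage 5


def extract_gap_contexts(assembly: Assembly, flank: int) -> list[GapContext]:
    """One context per N-run: up to ``flank`` bases on either side, truncated
    at scaffold ends and adjacent gaps."""
    contexts: list[GapContext] = []
    for si, scaf in enumerate(assembly.scaffolds):
        gaps = scaf.gaps
        for gi, (start, length) in enumerate(gaps):
            left_lim = 0 if gi == 0 else gaps[gi - 1][0] + gaps[gi - 1][1]
            right_lim = len(scaf) if gi == len(gaps) - 1 else gaps[gi + 1][0]
            lf_start = max(left_lim, start - flank)
            rf_end = min(right_lim, start + length + flank)
            contexts.append(GapContext(
                gap_id=f"{si}:{start}",
                left_flank=scaf.sequence[lf_start:start],
                right_flank=scaf.sequence[start + length:rf_end],
                scaffold_index=si,
                gap_interval=(start, start + length),
                flank_interval=(lf_start, rf_end),
            ))
    return contexts


def _noncontext_sequences(assembly: Assembly, contexts: list[GapContext]) -> list[str]:
    out: list[str] = []
    by_scaf: dict[int, list[tuple[int, int]]] = {}
    for ctx in contexts:
        by_scaf.setdefault(ctx.scaffold_index, []).append(ctx.flank_interval)
    for si, scaf in enumerate(assembly.scaffolds):
        ivals = sorted(by_scaf.get(si, []))
        pos = 0
        for s, e in ivals:
            if s > pos:
                out.append(scaf.sequence[pos:s])
            pos = max(pos, e)
        if pos < len(scaf):
            out.append(scaf.sequence[pos:])
    return [s for s in out if s]


def _filter_gap_reads(reads: ReadSet, positive: KmerTable, negative: KmerTable,
                      pair_policy: str) -> ReadSet:
    pos = select_reads(reads, positive, pair_policy)
    if len(negative) == 0:
        return pos
    hit = select_reads(pos, negative, "either_mate")
    bad_pairs = {id(p) for p in hit.pairs}
    bad_singles = {r.id for r in hit.singles}
    out = ReadSet(
        pairs=[p for p in pos.pairs if id(p) not in bad_pairs],
        singles=[r for r in pos.singles if r.id not in bad_singles],
    )
    return out


def _best_closure(ctx: GapContext, candidates: list[Scaffold],
                  config: PipelineConfig) -> str | None:
    """The best gap-closing sequence for one context, or None."""
    closures: list[tuple[tuple, str]] = []
    for cand in candidates:
        trio = Assembly.from_sequences([ctx.left_flank, cand.sequence, ctx.right_flank])
        try:
            merged = overlap_merge(trio, config.min_overlap, config.max_mismatch_rate)
        except ValueError:
            continue
        if merged.n_scaffolds != 1 or merged.n_gaps:
            continue
        seq = merged.scaffolds[0].sequence
        if ctx.left_flank not in seq and ctx.left_flank in revcomp(seq):
            seq = revcomp(seq)
        li = seq.find(ctx.left_flank)
        ri = seq.rfind(ctx.right_flank)
        if li < 0 or ri < 0 or ri < li + len(ctx.left_flank):
            continue
        closure = seq[li:ri + len(ctx.right_flank)]
        closures.append(((len(closure), closure), closure))
    if not closures:
        return None
    closures.sort(key=lambda c: c[0])
    return closures[0][1]


def run_stage5(reads: ReadSet, assembly: Assembly, config: PipelineConfig) -> StageState:
    """Gap filling with positive/negative k-mer read selection."""
    state = StageState(stage=5, best=assembly)
    state.record(0, assembly)
    if assembly.n_gaps == 0:
        state.terminated_because = "all_gaps_closed"
        return state
    current = assembly
    for it in range(1, config.max_iterations + 1):
        state.iteration = it
        contexts = extract_gap_contexts(current, config.gap_flank)
        flanks = [f for ctx in contexts for f in (ctx.left_flank, ctx.right_flank) if f]
        positive = count_kmers(flanks, config.k_count)
        rest = _noncontext_sequences(current, contexts)
        negative = table_difference(positive, count_kmers(rest, config.k_count))
        selected = _filter_gap_reads(reads, positive, negative, config.pair_policy)
        closed_any = False
        candidates: list[Scaffold] = []
        if selected.n_reads:
            batches = batch_subsample(selected, config.gap_batch, config.gap_batch,
                                      config.seed + it)
            assemblies = sweep_assemble(batches, config.K_values, _assemble_fn(config))
            for asm in assemblies:
                merged = overlap_merge(asm, config.min_overlap, config.max_mismatch_rate)
                for s in merged.scaffolds:
                    if len(s) >= asm.provenance.K:  # discard scaffolds shorter than K
                        candidates.append(s)
        new_scaffolds = [Scaffold(s.id, s.sequence, s.mean_coverage)
                         for s in current.scaffolds]
        for ctx in contexts:
            best = _best_closure(ctx, candidates, config) if candidates else None
            if best is None:
                continue
            scaf = new_scaffolds[ctx.scaffold_index]
            lf_start, rf_end = ctx.flank_interval
            scaf.sequence = scaf.sequence[:lf_start] + best + scaf.sequence[rf_end:]
            closed_any = True
        if not closed_any:
            state.terminated_because = "no_improvement"
            return state
        current = current.replace_scaffolds(new_scaffolds)
        state.best = current
        state.record(it, current)
        if current.n_gaps == 0:
            state.terminated_because = "all_gaps_closed"
            return state
    state.terminated_because = "iteration_limit"
    return state


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    histogram: KmerHistogram
    band: tuple[int, int] | None
    final: Assembly | None
    layout: list[tuple[str, str]] | None
    states: dict[str, object] = field(default_factory=dict)


def run_pipeline(reads: ReadSet | Path | str, config: PipelineConfig,
                 band: tuple[int, int] | None = None,
                 auto_band: bool = True,
                 reference: list[str] | None = None,
                 outdir: Path | str | None = None,
                 stop_after: int = 5) -> PipelineResult:
    """Stages 1-5 end to end, persisting per-stage artifacts when ``outdir``
    is given.  Without a band and with ``auto_band`` off, the run halts after
    stage 1 so the frequency band can be chosen from the histograms."""
    if not isinstance(reads, ReadSet):
        reads = scan_input_directory(reads)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    # stage 1
    table = count_kmers(reads, config.k_count)
    hist = histogram(table)
    if out is not None:
        write_kmer_table(table, out / "stage1_kmers.tsv")
        for b in (1, 10, 25, 100, 250):
            write_histogram(hist, out / f"stage1_hist_bin{b}.tsv", b)
    result = PipelineResult(histogram=hist, band=band, final=None, layout=None)
    if stop_after <= 1:
        return result
    if band is None:
        if not auto_band:
            return result
        peaks = detect_peaks(hist)
        band = peaks.band
        result.states["peaks"] = peaks
        logger.info("detected peaks: SC=%d IR=%d band=%s", peaks.sc_mode,
                    peaks.ir_mode, band)
    result.band = band
    best = run_stage2(reads, band, config, reference=reference, table=table,
                      outdir=out)
    result.states["stage2"] = best
    result.final = best
    if out is not None:
        _write_assembly(best, out / "stage2_best.fasta")
    if stop_after <= 2:
        return result
    s3 = run_stage3(reads, best, config, reference=reference)
    result.states["stage3"] = s3
    result.final = s3.best
    if out is not None:
        _write_assembly(s3.best, out / "stage3_best.fasta")
    if stop_after <= 3:
        return result
    s4 = run_stage4(reads, s3.best, config, reference=reference)
    result.states["stage4"] = s4
    result.final = s4.best
    if out is not None:
        _write_assembly(s4.best, out / "stage4_best.fasta")
    if stop_after <= 4:
        return result
    s5 = run_stage5(reads, s4.best, config)
    result.states["stage5"] = s5
    result.final = s5.best
    if out is not None:
        _write_assembly(s5.best, out / "stage5_best.fasta")
    if result.final.circular:
        result.layout = layout_outputs(result.final, config.output_layout,
                                       min_ir=config.min_ir, seed=config.seed)
        if out is not None:
            write_fasta(result.layout, out / "final_layout.fasta")
    if out is not None:
        manifest = {
            "band": list(band) if band else None,
            "circular": result.final.circular,
            "n_scaffolds": result.final.n_scaffolds,
            "n_gaps": result.final.n_gaps,
            "total_length": result.final.total_length,
            "stages": {name: getattr(st, "terminated_because", None)
                       for name, st in result.states.items()},
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _write_assembly(asm: Assembly, path: Path) -> None:
    write_fasta([(f"{s.id} length={len(s)} circular={str(asm.circular).lower()}",
                  s.sequence) for s in asm.scaffolds], path)
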