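"""Internal De Bruijn assembler plus sweep filtering and ranking.

The assembler is node-centric on canonical K-mers: reads are decomposed into
K-mers, K-mers below a coverage cutoff are dropped, maximal unambiguous paths
(unitigs) are spelled as contigs, and short dead-end tips and low-coverage
bubbles are iteratively removed before the final unitig pass.  A light
paired-end scaffolding step joins contigs supported by enough read pairs
with unambiguous orientation, inserting N-runs.

An external assembler can be substituted through ``sweep_assemble``'s
``assemble_fn`` argument: any callable mapping ``(reads, K)`` to an
``Assembly`` satisfies the contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .dna import revcomp
from .io_formats import ReadSet
from .kmer_core import KmerTable, canonical_values_of, count_kmers, membership

logger = logging.getLogger(__name__)


def _canon(w: str, h: int) -> str:
    """Fast canonicalization for graph-internal ACGT-only K-mers."""
    return w if w[h] in "AC" else revcomp(w)

_N_RUN = re.compile(r"N+")


# ---------------------------------------------------------------------------
# assembly containers


@dataclass
class Scaffold:
    id: str
    sequence: str
    mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip("N")

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Maximal N-runs as (start, length)."""
        return [(m.start(), m.end() - m.start()) for m in _N_RUN.finditer(self.sequence)]

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Provenance:
    K: int = 0
    batch_size: int = 0
    stage: int = 0
    iteration: int = 0

    def order_key(self) -> tuple[int, int]:
        return (self.batch_size, self.K)


@dataclass
class Assembly:
    scaffolds: list[Scaffold] = field(default_factory=list)
    circular: bool = False
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        if self.circular and len(self.scaffolds) != 1:
            raise ValueError("a circular assembly must consist of exactly one scaffold")

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffolds)

    @property
    def n_gaps(self) -> int:
        return sum(s.n_gaps for s in self.scaffolds)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    @property
    def n_ambiguous(self) -> int:
        return sum(s.sequence.count("N") for s in self.scaffolds)

    def sequences(self) -> list[str]:
        return [s.sequence for s in self.scaffolds]

    def replace_scaffolds(self, scaffolds: list[Scaffold], circular: bool | None = None) -> "Assembly":
        return Assembly(
            scaffolds,
            self.circular if circular is None else circular,
            self.provenance,
        )

    @classmethod
    def from_sequences(
        cls,
        seqs: Iterable[str],
        circular: bool = False,
        provenance: Provenance | None = None,
        coverages: Sequence[float] | None = None,
    ) -> "Assembly":
        scaffolds = [
            Scaffold(f"s{i}", s, 0.0 if coverages is None else float(coverages[i]))
            for i, s in enumerate(seqs)
        ]
        return cls(scaffolds, circular, provenance or Provenance())


# ---------------------------------------------------------------------------
# De Bruijn graph


class _Graph:
    """Canonical-K-mer De Bruijn graph with string nodes."""

    def __init__(self, counts: dict[str, int], K: int):
        self.counts = counts
        self.K = K
        self.h = K // 2

    def right_exts(self, w: str) -> list[str]:
        suf = w[1:]
        h = self.h
        return [b for b in "ACGT" if _canon(suf + b, h) in self.counts]

    def left_exts(self, w: str) -> list[str]:
        pre = w[:-1]
        h = self.h
        return [a for a in "ACGT" if _canon(a + pre, h) in self.counts]

    def unitigs(self) -> list[tuple[str, float, bool]]:
        """Maximal unambiguous paths as (sequence, mean k-mer coverage, is_cycle).

        Deterministic: nodes are visited in sorted canonical order.
        """
        visited: set[str] = set()
        out: list[tuple[str, float, bool]] = []
        for start in sorted(self.counts):
            if start in visited:
                continue
            path = [start]
            members = {start}
            cycle = False
            # extend right
            w = start
            while True:
                nxt = self._step_right(w)
                if nxt is None:
                    break
                cn = _canon(nxt, self.h)
                if cn in members:
                    cycle = cn == _canon(path[0], self.h) and len(path) > 1
                    break
                if cn in visited:
                    break
                path.append(nxt)
                members.add(cn)
                w = nxt
            if not cycle:
                # extend left (walk right from the reverse complement of start)
                w = revcomp(start)
                left: list[str] = []
                while True:
                    nxt = self._step_right(w)
                    if nxt is None:
                        break
                    cn = _canon(nxt, self.h)
                    if cn in members or cn in visited:
                        break
                    left.append(nxt)
                    members.add(cn)
                    w = nxt
                path = [revcomp(x) for x in reversed(left)] + path
            visited.update(_canon(x, self.h) for x in path)
            seq = path[0] + "".join(x[-1] for x in path[1:])
            cov = float(np.mean([self.counts[_canon(x, self.h)] for x in path]))
            out.append((seq, cov, cycle))
        return out

    def _step_right(self, w: str) -> str | None:
        outs = self.right_exts(w)
        if len(outs) != 1:
            return None
        nxt = w[1:] + outs[0]
        if len(self.left_exts(nxt)) != 1:
            return None
        return nxt

    def remove_sequence(self, seq: str) -> None:
        K, h = self.K, self.h
        for i in range(len(seq) - K + 1):
            self.counts.pop(_canon(seq[i:i + K], h), None)


def _count_K(seqs: list[str], K: int, min_edge_coverage: int = 1) -> dict[str, int]:
    """Canonical K-mer counts above the coverage cutoff.

    The cutoff is the larger of ``min_edge_coverage`` and 10% of the
    volume-weighted mode of the solid-coverage distribution, which removes
    recurrent sequencing errors at high depth.  Filtering happens on the
    packed arrays before any string decoding.
    """
    table = count_kmers(seqs, K)
    if len(table) == 0:
        return {}
    cutoff = min_edge_coverage
    solid = table.counts[table.counts >= min_edge_coverage] if min_edge_coverage >= 2 \
        else np.empty(0, dtype=np.int64)
    if solid.size:
        freqs, nd = np.unique(solid, return_counts=True)
        mode = int(freqs[np.argmax(nd * freqs)])
        cutoff = max(cutoff, mode // 10)
    mask = table.counts >= cutoff
    sub = KmerTable(table.k, table.kmers[mask], table.counts[mask])
    return sub.as_dict()


def _simplify(graph: _Graph, K: int, rounds: int = 3) -> list[tuple[str, float, bool]]:
    """Iteratively drop short dead-end tips and low-coverage bubbles."""
    for _ in range(rounds):
        unis = graph.unitigs()
        if len(unis) <= 1:
            return unis
        to_remove: list[str] = []
        # adjacency signatures of unitig ends
        infos = []
        for seq, cov, cycle in unis:
            if cycle:
                infos.append(None)
                continue
            first, last = seq[:K], seq[-K:]
            h = K // 2
            left = frozenset(_canon(a + first[:-1], h) for a in graph.left_exts(first))
            right = frozenset(_canon(last[1:] + b, h) for b in graph.right_exts(last))
            infos.append((left, right))
        own = [
            {_canon(seq[i:i + K], K // 2) for i in range(len(seq) - K + 1)}
            if info is not None else set()
            for (seq, _, _), info in zip(unis, infos)
        ]
        # tips: one free end, shorter than 2K
        for (seq, cov, cycle), info, mine in zip(unis, infos, own):
            if info is None:
                continue
            left, right = info
            ldead = not (left - mine)
            rdead = not (right - mine)
            if (ldead != rdead) and len(seq) < 2 * K:
                to_remove.append(seq)
        # bubbles: same end adjacency on both sides, keep the best covered
        groups: dict[tuple, list[tuple[str, float]]] = {}
        for (seq, cov, cycle), info, mine in zip(unis, infos, own):
            if info is None:
                continue
            left, right = info
            lkey, rkey = left - mine, right - mine
            if not lkey or not rkey:
                continue
            key = tuple(sorted((tuple(sorted(lkey)), tuple(sorted(rkey)))))
            groups.setdefault(key, []).append((seq, cov))
        for members in groups.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda sc: (-sc[1], sc[0]))
            for seq, _ in members[1:]:
                to_remove.append(seq)
        if not to_remove:
            return unis
        for seq in to_remove:
            graph.remove_sequence(seq)
        if not graph.counts:
            return []
    return graph.unitigs()


def debruijn_assemble(
    reads: ReadSet | Iterable[str],
    K: int,
    min_edge_coverage: int = 3,
    min_links: int = 3,
    scaffold_pairs: bool = True,
    gap_n: int = 100,
) -> Assembly:
    """Assemble reads into contigs/scaffolds with a canonical De Bruijn graph.

    K-mers seen fewer than ``min_edge_coverage`` times are dropped before
    graph construction (with an additional adaptive cutoff at 10% of the
    main coverage mode, which removes recurrent sequencing errors at high
    depth); tips shorter than 2K and low-coverage bubbles are pruned.
    Deterministic for a given input order.
    """
    if K % 2 == 0 or K < 3:
        raise ValueError(f"K must be odd and >= 3, got {K}")
    if isinstance(reads, ReadSet):
        seqs = list(reads.iter_sequences())
        readset = reads
    else:
        seqs = list(reads)
        readset = None
    counts = _count_K(seqs, K, min_edge_coverage)
    if not counts:
        return Assembly(provenance=Provenance(K=K))
    graph = _Graph(counts, K)
    unis = _simplify(graph, K)
    unis.sort(key=lambda u: (-len(u[0]), u[0]))
    scaffolds = [Scaffold(f"s{i}", seq, cov) for i, (seq, cov, _) in enumerate(unis)]
    circular = len(unis) == 1 and unis[0][2]
    asm = Assembly(scaffolds, circular=circular, provenance=Provenance(K=K))
    if scaffold_pairs and readset is not None and readset.pairs and asm.n_scaffolds > 1:
        asm = _pair_scaffold(asm, readset, K, min_links, gap_n)
    return asm


def _pair_scaffold(asm: Assembly, reads: ReadSet, K: int, min_links: int, gap_n: int) -> Assembly:
    """Join contigs linked by >= min_links pairs with unambiguous orientation."""
    from .stages import map_reads  # local import to avoid a cycle

    seed_len = min(31, K)
    if seed_len % 2 == 0:
        seed_len -= 1
    alns = map_reads(reads, asm, seed_len=seed_len)
    links: dict[tuple[int, int], dict[tuple[str, str], int]] = {}
    for m1, m2 in reads.pairs:
        a1, a2 = alns.get(m1.id), alns.get(m2.id)
        if a1 is None or a2 is None or a1.scaffold == a2.scaffold:
            continue
        i, j = a1.scaffold, a2.scaffold
        # orient so the pair points i(+ end) -> j; a '+' mate points right
        key = (min(i, j), max(i, j))
        ori = (a1.strand, a2.strand) if i < j else (a2.strand, a1.strand)
        links.setdefault(key, {}).setdefault(ori, 0)
        links[key][ori] += 1
    joins: list[tuple[int, int, int, tuple[str, str]]] = []
    for (i, j), oris in links.items():
        ori, n = max(oris.items(), key=lambda kv: (kv[1], kv[0]))
        # a repeat contig (e.g. the IR) links its neighbours in two
        # orientations at once; require the runner-up to be noise-level
        runner_up = max((v for o, v in oris.items() if o != ori), default=0)
        if n >= min_links and runner_up < min_links:
            joins.append((n, i, j, ori))
    if not joins:
        return asm
    joins.sort(key=lambda t: (-t[0], t[1], t[2]))
    used: set[int] = set()
    merged: list[Scaffold] = []
    consumed: set[int] = set()
    for n, i, j, (s1, s2) in joins:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = asm.scaffolds[i].sequence, asm.scaffolds[j].sequence
        # FR orientation: mate on '+' points right, on '-' points left
        a_seq = a if s1 == "+" else revcomp(a)
        b_seq = b if s2 == "-" else revcomp(b)
        cov = (asm.scaffolds[i].mean_coverage + asm.scaffolds[j].mean_coverage) / 2
        merged.append(Scaffold(f"j{i}_{j}", a_seq + "N" * gap_n + b_seq, cov))
        consumed.update((i, j))
    out = [s for idx, s in enumerate(asm.scaffolds) if idx not in consumed] + merged
    out.sort(key=lambda s: (-len(s), s.sequence))
    for idx, s in enumerate(out):
        s.id = f"s{idx}"
    return asm.replace_scaffolds(out, circular=False)


# ---------------------------------------------------------------------------
# sweep, filters, ranking


def external_assembler(command_template: str, workdir: str | Path):
    """Adapter wrapping an external assembler behind the sweep contract.

    ``command_template`` is a shell template with ``{reads}``, ``{K}`` and
    ``{out}`` placeholders; the adapter writes the batch as FASTQ, runs the
    command, and reads the FASTA it produced.  Any failure raises, which
    ``sweep_assemble`` logs and skips.
    """
    import subprocess

    from .io_formats import read_fasta, write_fastq

    workdir = Path(workdir)

    def fn(batch: ReadSet, K: int) -> Assembly:
        workdir.mkdir(parents=True, exist_ok=True)
        prefix = workdir / f"batch_K{K}"
        paths = write_fastq(batch, prefix)
        out = workdir / f"assembly_K{K}.fasta"
        cmd = command_template.format(
            reads=" ".join(str(p) for p in paths), K=K, out=out)
        subprocess.run(cmd, shell=True, check=True, capture_output=True)
        records = read_fasta(out)
        return Assembly(
            [Scaffold(name or f"s{i}", seq) for i, (name, seq) in enumerate(records)],
            provenance=Provenance(K=K),
        )

    return fn


def sweep_assemble(
    batches: Sequence[ReadSet],
    K_values: Sequence[int],
    assemble_fn: Callable[[ReadSet, int], Assembly],
) -> list[Assembly]:
    """One assembly per (batch, K) pair, tagged with provenance.

    A failure of ``assemble_fn`` for one pair is logged and skipped.
    """
    if not batches or not K_values:
        raise ValueError("batches and K_values must be non-empty")
    out: list[Assembly] = []
    for batch in batches:
        size = batch.n_pairs + len(batch.singles)
        for K in K_values:
            try:
                asm = assemble_fn(batch, K)
            except Exception:  # noqa: BLE001 - adapter contract: skip, don't abort
                logger.exception("assembly failed for batch=%d K=%d; skipping", size, K)
                continue
            asm.provenance = Provenance(K=K, batch_size=size,
                                        stage=asm.provenance.stage,
                                        iteration=asm.provenance.iteration)
            out.append(asm)
    return out


def filter_homology(asm: Assembly, reference: Sequence[str] | None,
                    min_shared: float = 0.2, k: int = 31) -> Assembly:
    """Keep scaffolds sharing >= ``min_shared`` of their canonical k-mers
    with the reference (a containment proxy for a BLAST hit).  With no
    reference configured the filter is the identity."""
    if not reference:
        return asm
    ref_table = count_kmers(list(reference), k)
    kept: list[Scaffold] = []
    for s in asm.scaffolds:
        values, valid = canonical_values_of(s.sequence, k)
        values = values[valid]
        if values.size == 0:
            continue
        shared = membership(ref_table, values).mean()
        if shared >= min_shared:
            kept.append(s)
        else:
            logger.info("homology filter dropped %s (containment %.3f)", s.id, shared)
    return asm.replace_scaffolds(kept, circular=asm.circular and len(kept) == 1)


def filter_size(asm: Assembly, K: int) -> Assembly:
    """Remove scaffolds smaller than twice the size of K."""
    kept = [s for s in asm.scaffolds if len(s) >= 2 * K]
    return asm.replace_scaffolds(kept, circular=asm.circular and len(kept) == 1)


def sanity_check(asm: Assembly, size_total: tuple[int, int],
                 region_lengths: dict[str, int] | None = None,
                 size_regions: dict[str, tuple[int, int]] | None = None) -> bool:
    """True iff total length is within range (and annotated regions, if given)."""
    lo, hi = size_total
    if not (lo <= asm.total_length <= hi):
        return False
    if region_lengths and size_regions:
        for name, length in region_lengths.items():
            if name in size_regions:
                rlo, rhi = size_regions[name]
                if not (rlo <= length <= rhi):
                    return False
    return True


def ranking_key(asm: Assembly, mode: str = "lexicographic") -> tuple:
    """Sort key: smaller is better.

    ``lexicographic``: (n_scaffolds, n_gaps, -total_length) — fewer scaffolds
    first, then fewer gaps, then longest.  ``scaffolds_plus_gaps``:
    (n_scaffolds + n_gaps, -total_length).  Ties break on fewer N bases,
    then provenance order (smaller batch, smaller K).
    """
    if mode == "lexicographic":
        head: tuple = (asm.n_scaffolds, asm.n_gaps, -asm.total_length)
    elif mode == "scaffolds_plus_gaps":
        head = (asm.n_scaffolds + asm.n_gaps, -asm.total_length)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    return head + (asm.n_ambiguous, asm.provenance.order_key())


def rank_assemblies(assemblies: Sequence[Assembly], mode: str = "lexicographic") -> Assembly:
    """The best assembly under the chosen ranking mode (deterministic)."""
    if not assemblies:
        raise ValueError("no assembly survived filtering")
    return min(assemblies, key=lambda a: ranking_key(a, mode))
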