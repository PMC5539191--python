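"""Readers/writers and the pipeline configuration.

FASTQ input follows a simple file-naming convention: two files whose names
differ only in a mate token (``_1``/``_2``, ``_R1``/``_R2`` or ``.1``/``.2``
immediately before the ``.fastq``/``.fq`` extension) are treated as a
paired-end library and paired record-by-record; every other FASTQ file
contributes single-end reads.  Gzip-compressed files are read transparently.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .kmer_core import KmerHistogram, KmerTable

# ---------------------------------------------------------------------------
# read records


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str | None = None
    mate_role: str = "single"  # single | mate1 | mate2

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """Paired and single reads; the unit of selection and batching."""

    pairs: list[tuple[ReadRecord, ReadRecord]] = field(default_factory=list)
    singles: list[ReadRecord] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_reads(self) -> int:
        return 2 * len(self.pairs) + len(self.singles)

    def iter_records(self) -> Iterator[ReadRecord]:
        for m1, m2 in self.pairs:
            yield m1
            yield m2
        yield from self.singles

    def iter_sequences(self) -> Iterator[str]:
        for r in self.iter_records():
            yield r.sequence

    def __len__(self) -> int:
        return self.n_reads


# ---------------------------------------------------------------------------
# FASTQ scanning

_MATE_TOKENS = [
    (re.compile(r"_R1(?=\.)"), re.compile(r"_R2(?=\.)"), "_R{}"),
    (re.compile(r"_1(?=\.)"), re.compile(r"_2(?=\.)"), "_{}"),
    (re.compile(r"\.1(?=\.)"), re.compile(r"\.2(?=\.)"), ".{}"),
]
_FASTQ_EXT = re.compile(r"\.(fastq|fq)(\.gz)?$")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fastq(path: Path | str, mate_role: str = "single") -> list[ReadRecord]:
    path = Path(path)
    out: list[ReadRecord] = []
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                out.append(ReadRecord(title.split()[0], seq.upper(), qual, mate_role))
        except ValueError as exc:
            raise ValueError(f"{path}: bad FASTQ record #{len(out) + 1}: {exc}") from exc
    return out


def scan_input_directory(path: Path | str) -> ReadSet:
    """Collect all FASTQ files under ``path`` into a ReadSet.

    Files matching the mate-token convention are paired record-by-record;
    paired files of unequal record count are an error.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"input directory not found: {path}")
    files = sorted(p for p in path.iterdir() if _FASTQ_EXT.search(p.name))
    paired: dict[Path, Path] = {}
    claimed: set[Path] = set()
    for p in files:
        for tok1, tok2, _ in _MATE_TOKENS:
            if tok1.search(p.name):
                mate = p.with_name(tok1.sub(lambda m: m.group(0).replace("1", "2"), p.name))
                if mate in files and mate != p:
                    paired[p] = mate
                    claimed.update((p, mate))
                break
    rs = ReadSet()
    for p1 in sorted(paired):
        p2 = paired[p1]
        reads1 = read_fastq(p1, "mate1")
        reads2 = read_fastq(p2, "mate2")
        if len(reads1) != len(reads2):
            raise ValueError(
                f"paired files have unequal record counts: {p1} ({len(reads1)}) "
                f"vs {p2} ({len(reads2)})"
            )
        rs.pairs.extend(zip(reads1, reads2))
    for p in files:
        if p not in claimed:
            rs.singles.extend(read_fastq(p, "single"))
    return rs


def write_fastq(reads: ReadSet, prefix: Path | str) -> list[Path]:
    """Write a ReadSet as ``<prefix>_1.fastq``/``_2.fastq`` (+ ``<prefix>.fastq``)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _dump(records: Sequence[ReadRecord], p: Path) -> None:
        with open(p, "w") as fh:
            for r in records:
                q = r.quality if r.quality is not None else "I" * len(r)
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")
        written.append(p)

    if reads.pairs:
        _dump([m1 for m1, _ in reads.pairs], prefix.with_name(prefix.name + "_1.fastq"))
        _dump([m2 for _, m2 in reads.pairs], prefix.with_name(prefix.name + "_2.fastq"))
    if reads.singles:
        _dump(reads.singles, prefix.with_name(prefix.name + ".fastq"))
    return written


def write_fasta(records: Sequence[tuple[str, str]], path: Path | str, width: int = 70) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_fasta(path: Path | str) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    name, chunks = None, []
    with _open_text(Path(path)) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0] if line[1:] else "", []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


# ---------------------------------------------------------------------------
# k-mer table / histogram TSV


def write_kmer_table(table: KmerTable, path: Path | str) -> Path:
    """TSV ``kmer<TAB>count``, ascending lexicographic order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    keys = table.keys()
    if any(a >= b for a, b in zip(keys, keys[1:])):
        raise ValueError("k-mer table is not strictly sorted")
    with open(path, "w") as fh:
        for key, count in zip(keys, table.counts):
            fh.write(f"{key}\t{int(count)}\n")
    return path


def read_kmer_table(path: Path | str) -> KmerTable:
    entries: dict[str, int] = {}
    prev = ""
    k = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            kmer, count = parts
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise ValueError(f"{path}:{lineno}: k-mer length differs from first row")
            if kmer <= prev:
                raise ValueError(f"{path}:{lineno}: rows out of order ({kmer!r} after {prev!r})")
            try:
                entries[kmer] = int(count)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad count {count!r}") from None
            prev = kmer
    if k is None:
        raise ValueError(f"{path}: empty k-mer table file has no k; use KmerTable(k) directly")
    return KmerTable.from_dict(k, entries)


VALID_BIN_SIZES = (1, 10, 25, 100, 250)


def write_histogram(hist: KmerHistogram, path: Path | str, bin_size: int = 1) -> Path:
    """TSV ``bin_start<TAB>distinct_kmers<TAB>volume`` with half-open bins.

    Bins of width ``bin_size`` start at frequency 1: [1, 1+b), [1+b, 1+2b)...
    ``bin_size`` 1 writes the unbinned histogram.
    """
    if bin_size not in VALID_BIN_SIZES:
        raise ValueError(f"bin_size must be one of {VALID_BIN_SIZES}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    binned: dict[int, list[int]] = {}
    for f, (d, v) in sorted(hist.rows.items()):
        start = 1 + ((f - 1) // bin_size) * bin_size
        acc = binned.setdefault(start, [0, 0])
        acc[0] += d
        acc[1] += v
    with open(path, "w") as fh:
        fh.write("bin_start\tdistinct_kmers\tvolume\n")
        for start in sorted(binned):
            d, v = binned[start]
            fh.write(f"{start}\t{d}\t{v}\n")
    return path


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable parameters of the five-stage pipeline.

    Defaults follow the published protocol: counting k 31; assembly K sweep
    over all odd values 63..99; read-pair batches starting at 100,000 with
    100,000 increments; 500 bp gap flanks; 1000 read(-pair) gap batches.
    """

    k_count: int = 31
    K_values: tuple[int, ...] = tuple(range(63, 100, 2))
    batch_start: int = 100_000
    batch_increment: int = 100_000
    gap_flank: int = 500
    gap_batch: int = 1000
    # sanity length ranges (bases): total assembly and, when annotated, regions
    size_total: tuple[int, int] = (100_000, 250_000)
    size_lsc: tuple[int, int] = (60_000, 140_000)
    size_ssc: tuple[int, int] = (5_000, 30_000)
    size_ir: tuple[int, int] = (10_000, 60_000)
    max_iterations: int = 10
    ranking_mode: str = "lexicographic"  # or "scaffolds_plus_gaps"
    output_layout: str = "one_circular"  # three_linear | two_circular | one_circular
    seed: int = 0
    # internal assembler / scaffolder knobs (not fixed by the protocol)
    min_edge_coverage: int = 3
    min_links: int = 3
    min_overlap: int = 50
    max_mismatch_rate: float = 0.0
    gap_n: int = 100
    min_ir: int = 1000
    pair_policy: str = "either_mate"  # either_mate | both_mates | per_read
    end_window: int = 600  # how far from a scaffold end a read may anchor in stage 4
    min_homology: float = 0.2

    def __post_init__(self) -> None:
        for k in (self.k_count, *self.K_values):
            if k % 2 == 0 or k < 3:
                raise ValueError(f"all k values must be odd and >= 3, got {k}")
        if self.batch_start <= 0 or self.batch_increment <= 0 or self.gap_batch <= 0:
            raise ValueError("batch sizes must be positive")
        if self.gap_flank < self.k_count:
            raise ValueError("gap_flank must be >= k_count")
        if self.ranking_mode not in ("lexicographic", "scaffolds_plus_gaps"):
            raise ValueError(f"unknown ranking_mode {self.ranking_mode!r}")
        if self.output_layout not in ("three_linear", "two_circular", "one_circular"):
            raise ValueError(f"unknown output_layout {self.output_layout!r}")
        if self.pair_policy not in ("either_mate", "both_mates", "per_read"):
            raise ValueError(f"unknown pair_policy {self.pair_policy!r}")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("K_values",):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("size_total", "size_lsc", "size_ssc", "size_ir"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path


def toy_config(**overrides) -> PipelineConfig:
    """A small-genome profile used by the test fixtures and examples.

    Scales the protocol down to a few-kb plastome: K sweep {21, 31}, 5000
    read-pair batches, permissive toy sanity ranges, 30 bp merge overlaps and
    a 500 bp IR minimum.  Protocol-scale defaults remain in PipelineConfig.
    """
    base = dict(
        K_values=(21, 31),
        batch_start=5000,
        batch_increment=5000,
        gap_flank=300,
        size_total=(15_000, 45_000),
        size_lsc=(10_000, 30_000),
        size_ssc=(1_000, 10_000),
        size_ir=(2_000, 10_000),
        min_overlap=30,
        min_ir=500,
        max_iterations=5,
    )
    base.update(overrides)
    return PipelineConfig(**base)
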