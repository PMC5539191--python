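"""Canonical k-mer counting, frequency tables and volume histograms.

The pipeline's selection machinery is built on *ordinal* (canonical) k-mers:
a k-mer and its exact reverse complement are counted as one, and the
representative is the orientation whose middle nucleotide is A or C (which is
why k must be odd — exactly one of the two orientations qualifies).

For k <= 31 k-mers are packed two bits per base into uint64 with A=0, C=1,
G=2, T=3; numeric order of the packed values equals lexicographic order of
the strings, so the "alphabetically sorted k-mer table" is simply a sorted
integer array.  Larger k falls back to sorted string arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .dna import BASES, decode_codes, encode, revcomp

MAX_ENCODED_K = 31


class AmbiguousKmerError(ValueError):
    """Raised when a k-mer window contains a non-ACGT symbol."""


# ---------------------------------------------------------------------------
# canonicalization


def canonical_kmer(window: str) -> str:
    """Return the ordinal representative of ``window``.

    The window itself if its middle base is A or C, otherwise its reverse
    complement (whose middle base then is).  ``window`` must have odd length
    and contain only ACGT.
    """
    k = len(window)
    if k % 2 == 0:
        raise ValueError(f"k-mer length must be odd, got {k}")
    mid = window[k // 2]
    if mid in "AC":
        out = window
    elif mid in "GT":
        out = revcomp(window)
    else:
        raise AmbiguousKmerError(f"non-ACGT symbol in k-mer: {window!r}")
    if any(c not in BASES for c in out):
        raise AmbiguousKmerError(f"non-ACGT symbol in k-mer: {window!r}")
    return out


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string (len <= 31) into its 2-bit uint64 value."""
    v = 0
    for c in kmer:
        v = (v << 2) | "ACGT".index(c)
    return v


def decode_kmer(value: int, k: int) -> str:
    codes = np.empty(k, dtype=np.uint8)
    for j in range(k):
        codes[k - 1 - j] = (value >> (2 * j)) & 3
    return decode_codes(codes)


def _canonical_hashes(codes: np.ndarray, k: int):
    """Vectorized canonical k-mer values for every window of a code array.

    Returns ``(values, valid)`` where ``valid`` masks windows free of
    non-ACGT codes.  Windows are canonicalized by the middle-base rule.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = codes > 3
    cs = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(bad, out=cs[1:])
    valid = (cs[k:] - cs[:-k]) == 0
    c = np.where(bad, 0, codes).astype(np.uint64)
    two = np.uint64(2)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << two) | c[j:j + m]
    rc = (np.uint64(3) - c)[::-1]
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        rev = (rev << two) | rc[j:j + m]
    rev = rev[::-1]  # rev[i] is now the value of revcomp(window i)
    mid = codes[k // 2:k // 2 + m]
    return np.where(mid < 2, fwd, rev), valid


def decode_many(values: np.ndarray, k: int) -> list[str]:
    """Decode an array of packed k-mer values to strings."""
    v = np.asarray(values, dtype=np.uint64)
    cols = np.empty((v.size, k), dtype=np.uint8)
    for j in range(k):
        cols[:, k - 1 - j] = (v >> np.uint64(2 * j)).astype(np.uint64) & np.uint64(3)
    flat = decode_codes(cols.reshape(-1))
    return [flat[i * k:(i + 1) * k] for i in range(v.size)]


# ---------------------------------------------------------------------------
# tables


@dataclass
class KmerTable:
    """Sorted map from canonical k-mer to occurrence count.

    ``kmers`` is either a sorted uint64 array (encoded, k <= 31) or a sorted
    numpy unicode array; both sort orders coincide with lexicographic order
    of the k-mer strings.
    """

    k: int
    kmers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def encoded(self) -> bool:
        return self.kmers.dtype == np.uint64

    def __len__(self) -> int:
        return int(self.kmers.size)

    def __contains__(self, kmer: str) -> bool:
        key: object = encode_kmer(kmer) if self.encoded else kmer
        i = np.searchsorted(self.kmers, key)
        return bool(i < len(self) and self.kmers[i] == key)

    def get(self, kmer: str, default: int = 0) -> int:
        key: object = encode_kmer(kmer) if self.encoded else kmer
        i = np.searchsorted(self.kmers, key)
        if i < len(self) and self.kmers[i] == key:
            return int(self.counts[i])
        return default

    def keys(self) -> list[str]:
        if self.encoded:
            return decode_many(self.kmers, self.k)
        return [str(s) for s in self.kmers]

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.keys(), (int(c) for c in self.counts)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.items())

    @property
    def total_volume(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dict(cls, k: int, entries: dict[str, int]) -> "KmerTable":
        keys = sorted(entries)
        counts = np.array([entries[s] for s in keys], dtype=np.int64)
        if k <= MAX_ENCODED_K:
            arr = np.array([encode_kmer(s) for s in keys], dtype=np.uint64)
        else:
            arr = np.array(keys, dtype=f"<U{k}")
        return cls(k, arr, counts)


def _iter_sequences(reads) -> Iterator[str]:
    # Accepts a ReadSet, an iterable of strings, or of objects with .sequence
    if hasattr(reads, "iter_sequences"):
        yield from reads.iter_sequences()
        return
    for item in reads:
        yield item.sequence if hasattr(item, "sequence") else item


def count_kmers(reads, k: int) -> KmerTable:
    """Count canonical k-mers over every window of every read.

    Windows containing N (or any non-ACGT symbol) are skipped; reads shorter
    than k contribute nothing.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    seqs = list(_iter_sequences(reads))
    if k <= MAX_ENCODED_K:
        if not seqs:
            return KmerTable(k)
        big = "N".join(seqs)
        values, valid = _canonical_hashes(encode(big), k)
        values = values[valid]
        if values.size == 0:
            return KmerTable(k)
        kmers, counts = np.unique(values, return_counts=True)
        return KmerTable(k, kmers, counts.astype(np.int64))
    # string fallback for k > 31 (used by the wide-K assembly sweep)
    d: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            try:
                c = canonical_kmer(w)
            except AmbiguousKmerError:
                continue
            d[c] = d.get(c, 0) + 1
    return KmerTable.from_dict(k, d)


def canonical_values_of(seq: str, k: int):
    """(values, valid) canonical window values of one sequence; k <= 31 only."""
    if k > MAX_ENCODED_K:
        raise ValueError("encoded canonical values require k <= 31")
    return _canonical_hashes(encode(seq), k)


# ---------------------------------------------------------------------------
# histograms


@dataclass
class KmerHistogram:
    """frequency -> (distinct k-mers, volume = distinct * frequency)."""

    k: int
    rows: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def total_volume(self) -> int:
        return sum(v for _, v in self.rows.values())

    @property
    def total_distinct(self) -> int:
        return sum(d for d, _ in self.rows.values())


def histogram(table: KmerTable) -> KmerHistogram:
    """k-mer frequency histogram of a table: distinct and volume per frequency."""
    if len(table) == 0:
        return KmerHistogram(table.k)
    freqs, distinct = np.unique(table.counts, return_counts=True)
    rows = {int(f): (int(d), int(d) * int(f)) for f, d in zip(freqs, distinct)}
    return KmerHistogram(table.k, rows)


# ---------------------------------------------------------------------------
# table algebra


def select_kmers_by_frequency(table: KmerTable, f_min: int, f_max: int | float) -> KmerTable:
    """Subset of entries with f_min <= count <= f_max (order preserved)."""
    if f_min < 1 or f_min > f_max:
        raise ValueError(f"bad frequency range [{f_min}, {f_max}]")
    mask = (table.counts >= f_min) & (table.counts <= f_max)
    return KmerTable(table.k, table.kmers[mask], table.counts[mask])


def table_difference(positive: KmerTable, other: KmerTable) -> KmerTable:
    """Entries of ``other`` whose k-mer is absent from ``positive``."""
    if positive.k != other.k:
        raise ValueError(f"k mismatch: {positive.k} vs {other.k}")
    if len(positive) == 0 or len(other) == 0:
        return KmerTable(other.k, other.kmers.copy(), other.counts.copy())
    idx = np.searchsorted(positive.kmers, other.kmers)
    idx_c = np.clip(idx, 0, len(positive) - 1)
    present = positive.kmers[idx_c] == other.kmers
    present &= idx < len(positive)
    mask = ~present
    return KmerTable(other.k, other.kmers[mask], other.counts[mask])


def membership(table: KmerTable, values: np.ndarray) -> np.ndarray:
    """Boolean mask of which packed k-mer values occur in the table."""
    if len(table) == 0 or values.size == 0:
        return np.zeros(values.size, dtype=bool)
    idx = np.searchsorted(table.kmers, values)
    idx_c = np.clip(idx, 0, len(table) - 1)
    hit = table.kmers[idx_c] == values
    hit &= idx < len(table)
    return hit
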