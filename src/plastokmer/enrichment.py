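"""Chloroplast peak detection and k-mer-band read selection.

Because the two inverted-repeat copies of a plastome are exact reverse
complements, IR-derived k-mers occur at exactly twice the frequency of
single-copy (LSC/SSC) k-mers.  The volume histogram of a whole-genome
shotgun dataset therefore shows a characteristic peak pair with a 2x
frequency relation, riding above the error peak (frequency ~1) and the
nuclear-genome peak.  The published protocol locates this pair by eye;
``detect_peaks`` automates the same decision and the manual band can always
be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io_formats import ReadRecord, ReadSet
from .kmer_core import KmerHistogram, KmerTable, canonical_values_of, membership


class NoPeakPairError(RuntimeError):
    """No local-maxima pair with the 2x frequency relation was found."""


@dataclass
class PeakCall:
    sc_mode: int          # frequency of the single-copy peak
    ir_mode: int          # frequency of the inverted-repeat peak (~2x sc_mode)
    band: tuple[int, int]  # selection range covering both peaks
    score: float          # summed smoothed volume at the two modes

    @property
    def ratio(self) -> float:
        return self.ir_mode / self.sc_mode


def _dense_volume(hist: KmerHistogram) -> np.ndarray:
    fmax = max(hist.rows)
    v = np.zeros(fmax + 1, dtype=float)
    for f, (_, vol) in hist.rows.items():
        v[f] = vol
    return v


def detect_peaks(
    hist: KmerHistogram,
    tolerance: float = 0.15,
    error_floor: int | None = None,
    smooth_window: int = 5,
) -> PeakCall:
    """Locate the SC/IR chloroplast peak pair on a volume histogram.

    The volume histogram is smoothed with a centred moving average, local
    maxima above ``error_floor`` are found, and among pairs (p, q) with
    ``|q - 2p| <= tolerance * 2p`` the pair with the largest summed volume is
    returned.  ``error_floor`` defaults to the first local minimum of the
    smoothed curve (the valley right of the error peak).
    """
    if not hist.rows:
        raise ValueError("empty histogram")
    v = _dense_volume(hist)
    w = max(1, smooth_window)
    kernel = np.ones(w) / w
    vs = np.convolve(v, kernel, mode="same")
    if error_floor is None:
        # first valley after the error peak; fall back to a small constant
        mins, _ = find_peaks(-vs[1:])
        error_floor = int(mins[0]) + 1 if mins.size else 3
        error_floor = max(error_floor, 3)
    peaks, _ = find_peaks(vs)
    peaks = peaks[peaks > error_floor]
    best: PeakCall | None = None
    for p in peaks:
        for q in peaks:
            if q <= p:
                continue
            if abs(q - 2 * p) > tolerance * 2 * p:
                continue
            score = float(vs[p] + vs[q])
            if best is None or score > best.score:
                f_min = max(int(p // 2), error_floor + 1)
                f_max = int(3 * q // 2)
                best = PeakCall(int(p), int(q), (f_min, f_max), score)
    if best is None:
        raise NoPeakPairError(
            "no chloroplast peak pair found; set the k-mer frequency band manually"
        )
    return best


def _read_matches(record: ReadRecord, kmers: KmerTable) -> bool:
    if len(record) < kmers.k or len(kmers) == 0:
        return False
    values, valid = canonical_values_of(record.sequence, kmers.k)
    return bool(membership(kmers, values[valid]).any())


def _bulk_matches(records: list[ReadRecord], kmers: KmerTable) -> np.ndarray:
    """Which records contain >= 1 table k-mer, in one vectorized pass."""
    if not records or len(kmers) == 0:
        return np.zeros(len(records), dtype=bool)
    if not kmers.encoded:
        return np.array([_read_matches(r, kmers) for r in records], dtype=bool)
    seqs = [r.sequence for r in records]
    big = "N".join(seqs)
    values, valid = canonical_values_of(big, kmers.k)
    hit = membership(kmers, values)
    hit &= valid
    out = np.zeros(len(seqs), dtype=bool)
    w = np.flatnonzero(hit)
    if w.size:
        lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
        starts = np.concatenate(([0], np.cumsum(lens + 1)[:-1]))
        ridx = np.searchsorted(starts, w, side="right") - 1
        out[np.unique(ridx)] = True
    return out


def select_reads(reads: ReadSet, kmers: KmerTable, pair_policy: str = "either_mate") -> ReadSet:
    """Keep reads containing at least one k-mer from ``kmers``.

    Pair policies: ``either_mate`` keeps the pair when either mate matches
    (default — keeps pairs intact for the assembler), ``both_mates`` requires
    both, ``per_read`` splits non-matching mates off (matching mate becomes a
    single).  Input order is preserved.
    """
    if pair_policy not in ("either_mate", "both_mates", "per_read"):
        raise ValueError(f"unknown pair_policy {pair_policy!r}")
    out = ReadSet()
    hits1 = _bulk_matches([m1 for m1, _ in reads.pairs], kmers)
    hits2 = _bulk_matches([m2 for _, m2 in reads.pairs], kmers)
    for (m1, m2), hit1, hit2 in zip(reads.pairs, hits1, hits2):
        if pair_policy == "either_mate":
            if hit1 or hit2:
                out.pairs.append((m1, m2))
        elif pair_policy == "both_mates":
            if hit1 and hit2:
                out.pairs.append((m1, m2))
        elif pair_policy == "per_read":
            if hit1 and hit2:
                out.pairs.append((m1, m2))
            elif hit1:
                out.singles.append(m1)
            elif hit2:
                out.singles.append(m2)
    for r, hit in zip(reads.singles, _bulk_matches(reads.singles, kmers)):
        if hit:
            out.singles.append(r)
    return out


def select_kmers_by_bands(table: KmerTable, bands) -> KmerTable:
    """Union of several frequency bands (two-interval selection mode).

    ``bands`` is an iterable of (f_min, f_max); the single-interval band
    remains the default elsewhere.
    """
    mask = np.zeros(len(table), dtype=bool)
    for f_min, f_max in bands:
        if f_min < 1 or f_min > f_max:
            raise ValueError(f"bad frequency range [{f_min}, {f_max}]")
        mask |= (table.counts >= f_min) & (table.counts <= f_max)
    return KmerTable(table.k, table.kmers[mask], table.counts[mask])


def batch_subsample(reads: ReadSet, start: int, increment: int, seed: int) -> list[ReadSet]:
    """Nested batches of increasing size from one seeded shuffle.

    Batch sizes are ``start, start + increment, ...`` in read-pair units
    (singles count as one unit); the final batch is always the full set.
    Each batch is a prefix of the same shuffled order, so batches are nested
    and deterministic for a given seed.
    """
    if start <= 0 or increment <= 0:
        raise ValueError("start and increment must be positive")
    rng = np.random.default_rng(seed)
    units: list[tuple[ReadRecord, ReadRecord] | ReadRecord] = [*reads.pairs, *reads.singles]
    order = rng.permutation(len(units))
    shuffled = [units[i] for i in order]
    sizes: list[int] = []
    size = start
    while size < len(units):
        sizes.append(size)
        size += increment
    sizes.append(len(units))
    batches: list[ReadSet] = []
    for s in sizes:
        b = ReadSet()
        for u in shuffled[:s]:
            if isinstance(u, tuple):
                b.pairs.append(u)
            else:
                b.singles.append(u)
        batches.append(b)
    return batches
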