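"""Ground-truth simulator: plastome + nuclear background + paired-end reads.

The simulated plastome has the canonical LSC + IR + SSC + revcomp(IR)
architecture on a circle, present at high per-base coverage; the nuclear
background is a larger random sequence, optionally carrying repeat families
at chosen copy numbers (whose k-mers then occur at copy_number x
nuclear_coverage — deliberately able to collide with the chloroplast band).
Reads are uniform paired-end with substitution errors only; read ids encode
the origin (``pt``/``nc``) and source coordinates, so tests can score
selection and assembly against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dna import decode_codes, encode, random_seq, revcomp
from .io_formats import ReadRecord, ReadSet


@dataclass
class PlastomeTruth:
    lsc: str
    ir: str
    ssc: str

    @property
    def circle(self) -> str:
        return self.lsc + self.ir + self.ssc + revcomp(self.ir)

    def __len__(self) -> int:
        return len(self.lsc) + 2 * len(self.ir) + len(self.ssc)


@dataclass
class ReadSimParams:
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    substitution_error_rate: float = 0.01
    plastome_coverage: float = 100.0   # per-base coverage of the circle (= SC depth)
    nuclear_coverage: float = 2.0
    nuclear_size: int = 100_000
    repeat_families: tuple[tuple[int, int], ...] = ()  # (unit length, copy number)
    seed: int = 0
    coverage_hole: tuple[int, int] | None = None  # zero plastome sampling here

    def __post_init__(self) -> None:
        if self.plastome_coverage < 0 or self.nuclear_coverage < 0:
            raise ValueError("coverage values must be >= 0")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")

    def replace(self, **kw) -> "ReadSimParams":
        return replace(self, **kw)


def make_plastome(lsc_len: int, ir_len: int, ssc_len: int, seed: int) -> PlastomeTruth:
    """Uniform-random plastome with the LSC-IR-SSC-IR circle architecture."""
    if not (lsc_len >= ssc_len >= 0) or ir_len <= 0:
        raise ValueError("require lsc_len >= ssc_len >= 0 and ir_len > 0")
    rng = np.random.default_rng(seed)
    return PlastomeTruth(
        lsc=random_seq(lsc_len, rng),
        ir=random_seq(ir_len, rng),
        ssc=random_seq(ssc_len, rng),
    )


def make_nuclear(size: int, repeat_families: Sequence[tuple[int, int]], seed: int) -> str:
    """Random nuclear background with repeat units at stated copy numbers."""
    total_repeat = sum(u * c for u, c in repeat_families)
    if size < total_repeat:
        raise ValueError("nuclear size smaller than total repeat content")
    rng = np.random.default_rng(seed)
    seq = list(random_seq(size, rng))
    for unit_len, copies in repeat_families:
        unit = random_seq(unit_len, rng)
        starts = rng.integers(0, size - unit_len + 1, size=copies)
        for s in starts:
            seq[s:s + unit_len] = unit
    return "".join(seq)


def _sample_source(name: str, source: str, circular: bool, params: ReadSimParams,
                   coverage: float, rng: np.random.Generator,
                   hole: tuple[int, int] | None) -> list[tuple[ReadRecord, ReadRecord]]:
    L = len(source)
    rl = params.read_length
    if L == 0 or coverage <= 0 or L < rl:
        return []
    n_pairs = int(round(coverage * L / (2 * rl)))
    doubled = source + source if circular else source
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    lens = np.clip(np.round(rng.normal(params.insert_mean, params.insert_sd, n_pairs)),
                   rl, min(L, 4 * params.insert_mean)).astype(int)
    if circular:
        starts = rng.integers(0, L, size=n_pairs)
    else:
        starts = rng.integers(0, np.maximum(1, L - lens + 1))
    flips = rng.random(n_pairs) < 0.5
    err = params.substitution_error_rate
    for i in range(n_pairs):
        start, flen = int(starts[i]), int(lens[i])
        end = start + flen
        if hole is not None:
            h0, h1 = hole
            span = [(start, min(end, L)), (0, end - L)] if (circular and end > L) \
                else [(start, end)]
            if any(a < h1 and h0 < b for a, b in span):
                continue
        frag = doubled[start:end]
        r1, r2 = frag[:rl], revcomp(frag[-rl:])
        if flips[i]:
            r1, r2 = revcomp(frag[-rl:]), frag[:rl]
        if err > 0:
            r1 = _mutate(r1, err, rng)
            r2 = _mutate(r2, err, rng)
        stem = f"{name}_{i}_{start}"
        pairs.append((
            ReadRecord(f"{stem}/1", r1, "I" * rl, "mate1"),
            ReadRecord(f"{stem}/2", r2, "I" * rl, "mate2"),
        ))
    return pairs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    codes = encode(seq).copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    codes[pos] = (codes[pos] + shift) % 4
    return decode_codes(codes)


def simulate_reads(truth: PlastomeTruth | None, nuclear: str | None,
                   params: ReadSimParams) -> ReadSet:
    """Paired-end reads from the plastome circle (positions wrap) and the
    nuclear background, with substitution errors; deterministic per seed.

    Read ids are ``pt_<pair>_<pos>/<mate>`` and ``nc_<pair>_<pos>/<mate>``.
    """
    rng = np.random.default_rng(params.seed)
    rs = ReadSet()
    if truth is not None:
        rs.pairs.extend(_sample_source("pt", truth.circle, True, params,
                                       params.plastome_coverage, rng,
                                       params.coverage_hole))
    if nuclear:
        rs.pairs.extend(_sample_source("nc", nuclear, False, params,
                                       params.nuclear_coverage, rng, None))
    return rs


def read_origin(read_id: str) -> str:
    """'plastome' or 'nuclear', decoded from a simulated read id."""
    return "plastome" if read_id.startswith("pt_") else "nuclear"


def plastome_fraction(reads: ReadSet) -> float:
    """Fraction of read pairs (and singles) of plastome origin."""
    units = [m1.id for m1, _ in reads.pairs] + [r.id for r in reads.singles]
    if not units:
        return 0.0
    return sum(read_origin(u) == "plastome" for u in units) / len(units)
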