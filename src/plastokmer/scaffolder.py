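"""Overlap-based scaffold merging aware of circularity and the inverted repeat.

A plastome is a circle LSC + IR + SSC + revcomp(IR).  In a canonical De
Bruijn assembly the two IR copies collapse onto one contig, which therefore
legitimately overlaps *two* partners at each end.  ``overlap_merge``
recognises this situation and duplicates the repeat contig instead of
rejecting the merges as a conflict, which is what lets a three-contig
{LSC, IR, SSC} assembly close into the full circle.

Also here: pseudo-circularization, IR/LSC/SSC annotation of a circular
sequence, the final layout modes, and N-bridging of scaffold ends from a
read-pair connectivity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembler import Assembly, Scaffold
from .dna import revcomp

logger = logging.getLogger(__name__)

End = tuple[int, str]  # (instance index, "L" | "R")


class NoInvertedRepeatError(RuntimeError):
    """No inverted repeat above the configured minimum length was found."""


# ---------------------------------------------------------------------------
# overlap detection


def _longest_overlap(a: str, b: str, min_overlap: int, max_mismatch_rate: float = 0.0) -> int:
    """Longest t with suffix(a) matching prefix(b), min_overlap <= t < min(len).

    Exact by default; with a mismatch budget the first 12 junction bases must
    still match exactly (they seed the search).  Returns 0 if none.
    """
    limit = min(len(a), len(b))
    if limit <= min_overlap:
        return 0
    seed = b[:min_overlap] if max_mismatch_rate == 0 else b[:12]
    p = a.find(seed)
    while p != -1:
        t = len(a) - p
        if min_overlap <= t < limit:
            if max_mismatch_rate == 0:
                if a[p:] == b[:t]:
                    return t
            else:
                x = np.frombuffer(a[p:].encode(), dtype=np.uint8)
                y = np.frombuffer(b[:t].encode(), dtype=np.uint8)
                if (x != y).mean() <= max_mismatch_rate:
                    return t
        p = a.find(seed, p + 1)
    return 0


# ---------------------------------------------------------------------------
# chain machinery (shared by overlap_merge and rescaffold_with_matrix)


@dataclass
class _Chain:
    items: list[tuple[int, str]]          # (instance, orient)
    junctions: list[tuple[str, int]] = field(default_factory=list)  # ("ovl", t) | ("gap", n)
    closing: tuple[str, int] | None = None

    def flip(self) -> None:
        self.items = [(i, "-" if o == "+" else "+") for i, o in reversed(self.items)]
        self.junctions = list(reversed(self.junctions))

    @property
    def left_end(self) -> End:
        i, o = self.items[0]
        return (i, "L" if o == "+" else "R")

    @property
    def right_end(self) -> End:
        i, o = self.items[-1]
        return (i, "R" if o == "+" else "L")


class _ChainSet:
    def __init__(self, seqs: list[str]):
        self.seqs = seqs
        self.chains: dict[int, _Chain] = {i: _Chain([(i, "+")]) for i in range(len(seqs))}
        self.chain_of = {i: i for i in range(len(seqs))}

    def _locate(self, end: End) -> tuple[int, _Chain] | None:
        cid = self.chain_of[end[0]]
        chain = self.chains[cid]
        if chain.closing is not None:
            return None
        if end in (chain.left_end, chain.right_end):
            return cid, chain
        return None

    def join(self, end_a: End, end_b: End, junction: tuple[str, int]) -> bool:
        """Connect two free chain ends; returns False if either is unavailable.

        Joining the two ends of one chain closes it into a circle.
        """
        la, lb = self._locate(end_a), self._locate(end_b)
        if la is None or lb is None:
            return False
        (ca, chain_a), (cb, chain_b) = la, lb
        if ca == cb:
            if {end_a, end_b} == {chain_a.left_end, chain_a.right_end} and (
                len(chain_a.items) > 1 or end_a != end_b
            ):
                if chain_a.right_end != end_a:
                    chain_a.flip()
                chain_a.closing = junction
                return True
            return False
        if chain_a.right_end != end_a:
            chain_a.flip()
        if chain_b.left_end != end_b:
            chain_b.flip()
        chain_a.items.extend(chain_b.items)
        chain_a.junctions.append(junction)
        chain_a.junctions.extend(chain_b.junctions)
        for i, _ in chain_b.items:
            self.chain_of[i] = ca
        del self.chains[cb]
        return True

    def spell(self) -> list[tuple[str, bool]]:
        """Sequences of all chains as (sequence, is_circular), deterministic."""
        out = []
        for cid in sorted(self.chains):
            chain = self.chains[cid]
            i0, o0 = chain.items[0]
            seq = self.seqs[i0] if o0 == "+" else revcomp(self.seqs[i0])
            for (i, o), (kind, n) in zip(chain.items[1:], chain.junctions):
                nxt = self.seqs[i] if o == "+" else revcomp(self.seqs[i])
                if kind == "ovl":
                    seq += nxt[n:]
                else:
                    seq += "N" * n + nxt
            circular = chain.closing is not None
            if circular:
                kind, n = chain.closing
                if kind == "ovl":
                    seq = seq[:-n] if n else seq
                else:
                    # rotate so the closing N-run sits mid-sequence rather
                    # than being stripped as a trailing gap
                    seq += "N" * n
                    i0len = len(self.seqs[chain.items[0][0]])
                    pivot = max(1, i0len // 2)
                    seq = seq[pivot:] + seq[:pivot]
            out.append((seq, circular))
        return out


# ---------------------------------------------------------------------------
# overlap merge


def _drop_contained(seqs: list[str]) -> list[str]:
    keep: list[str] = []
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    for i in order:
        s, r = seqs[i], revcomp(seqs[i])
        if any(s in t or r in t for t in keep):
            continue
        keep.append(s)
    return keep


def overlap_merge(asm: Assembly, min_overlap: int = 50,
                  max_mismatch_rate: float = 0.0) -> Assembly:
    """Repeatedly merge scaffolds sharing end overlaps, longest first.

    A scaffold whose own end overlaps its own start closes into a circular
    assembly.  A scaffold whose ends each overlap two partners (the collapsed
    inverted repeat) is duplicated so both junction pairs can be made.
    Unmergeable scaffolds pass through unchanged.
    """
    if min_overlap < 20:
        raise ValueError("min_overlap must be >= 20")
    if asm.circular:
        return asm
    seqs = _drop_contained([s.sequence for s in asm.scaffolds])
    if not seqs:
        return asm.replace_scaffolds([], circular=False)

    def _records(seqs: list[str]):
        recs: dict[frozenset | tuple, tuple[int, End, End]] = {}
        n = len(seqs)
        for i in range(n):
            for j in range(n):
                for side_a in "RL":
                    for side_b in "LR":
                        if i == j and (side_a, side_b) != ("R", "L"):
                            continue
                        a = seqs[i] if side_a == "R" else revcomp(seqs[i])
                        b = seqs[j] if side_b == "L" else revcomp(seqs[j])
                        t = _longest_overlap(a, b, min_overlap, max_mismatch_rate)
                        if t:
                            ea, eb = (i, side_a), (j, side_b)
                            key = (ea, eb) if ea <= eb else (eb, ea)
                            old = recs.get(key)
                            if old is None or t > old[0]:
                                recs[key] = (t, ea, eb)
        return list(recs.values())

    records = _records(seqs)
    # ends with multiple partners: candidate inverted repeats
    end_use: dict[End, list[tuple[int, End, End]]] = {}
    for rec in records:
        end_use.setdefault(rec[1], []).append(rec)
        end_use.setdefault(rec[2], []).append(rec)
    dup_of: dict[int, int] = {}
    for i in range(len(seqs)):
        lrecs = sorted(end_use.get((i, "L"), []), key=lambda r: (-r[0], r[1], r[2]))
        rrecs = sorted(end_use.get((i, "R"), []), key=lambda r: (-r[0], r[1], r[2]))
        if len(lrecs) >= 2 and len(rrecs) >= 2:
            # duplicate the repeat contig; the second record at each end is
            # re-pointed at the copy (chains orient instances freely)
            new = len(seqs)
            seqs.append(seqs[i])
            dup_of[new] = i
            logger.info("duplicating putative IR contig %d (len %d)", i, len(seqs[i]))
            for rec in (lrecs[1], rrecs[1]):
                records.remove(rec)
                t, ea, eb = rec
                ea = (new, ea[1]) if ea[0] == i else ea
                eb = (new, eb[1]) if eb[0] == i else eb
                records.append((t, ea, eb))

    def _greedy(recs: list[tuple[int, End, End]]) -> list[tuple[str, bool]]:
        chains = _ChainSet(list(seqs))
        for t, ea, eb in sorted(recs, key=lambda r: (-r[0], r[1], r[2])):
            chains.join(ea, eb, ("ovl", t))
        spelled = chains.spell()
        spelled.sort(key=lambda sc: (-len(sc[0]), sc[0]))
        return spelled

    spelled = _greedy(records)
    if not (len(spelled) == 1 and spelled[0][1]):
        # the expected outcome is one circle; a large overlap between the
        # reverse-complement arms of the two IR copies can out-rank the true
        # junctions and orphan a single-copy contig.  Retry without
        # same-side records whose ends are both contested.
        end_count: dict[End, int] = {}
        for t, ea, eb in records:
            end_count[ea] = end_count.get(ea, 0) + 1
            end_count[eb] = end_count.get(eb, 0) + 1
        pruned = [
            (t, ea, eb) for t, ea, eb in records
            if not (ea[1] == eb[1] and end_count[ea] > 1 and end_count[eb] > 1)
        ]
        if len(pruned) < len(records):
            retry = _greedy(pruned)
            better = (len(retry) == 1 and retry[0][1],
                      -len(retry), sum(len(s) for s, _ in retry))
            worse = (len(spelled) == 1 and spelled[0][1],
                     -len(spelled), sum(len(s) for s, _ in spelled))
            if better > worse:
                spelled = retry
    circular = len(spelled) == 1 and spelled[0][1]
    scaffolds = [Scaffold(f"m{i}", s) for i, (s, _) in enumerate(spelled)]
    return asm.replace_scaffolds(scaffolds, circular=circular)


# ---------------------------------------------------------------------------
# pseudo-circularization


def pseudo_circularize(asm: Assembly, n: int) -> Assembly:
    """Append a copy of the first n bases to the end of a circular assembly.

    The result is linear, length L + n; reads spanning the origin can then be
    mapped across it.
    """
    if not asm.circular:
        raise ValueError("pseudo-circularization requires a circular assembly")
    seq = asm.scaffolds[0].sequence
    if n < 0 or n > len(seq):
        raise ValueError(f"n must be in [0, {len(seq)}], got {n}")
    out = Scaffold(asm.scaffolds[0].id + "_pseudocirc", seq + seq[:n],
                   asm.scaffolds[0].mean_coverage)
    return asm.replace_scaffolds([out], circular=False)


# ---------------------------------------------------------------------------
# inverted repeat detection and layout


@dataclass
class PlastomeLayout:
    lsc: str
    ir: str
    ssc: str
    orientation: str = "A"  # which of the two SSC orientations was taken

    @property
    def circular_sequence(self) -> str:
        return self.lsc + self.ir + self.ssc + revcomp(self.ir)


def find_inverted_repeat(sequence: str, min_ir: int = 1000, seed_k: int = 25
                         ) -> tuple[tuple[tuple[int, int], tuple[int, int]],
                                    tuple[int, int], tuple[int, int]]:
    """Locate the longest pair of disjoint reverse-complement intervals on a circle.

    Intervals are 0-based half-open on the circle; an interval may wrap (its
    end index then exceeds the circle length).  Returns
    ``((ir1, ir2), lsc_interval, ssc_interval)`` with the longer remaining
    arc labelled LSC.  Seeded by shared ``seed_k``-mers between the doubled
    sequence and its reverse complement, extended maximally.
    """
    L = len(sequence)
    if L < 2 * min_ir:
        raise NoInvertedRepeatError(f"sequence ({L} bp) shorter than two IR copies")
    s2 = sequence + sequence
    k = seed_k
    pos: dict[str, list[int]] = {}
    for i in range(len(s2) - k + 1):
        pos.setdefault(s2[i:i + k], []).append(i)
    # anti-diagonal runs: s2[i:i+k] == revcomp(s2[j:j+k]) keeps i+j constant
    diags: dict[int, list[int]] = {}
    for i in range(len(s2) - k + 1):
        w = revcomp(s2[i:i + k])
        for j in pos.get(w, ()):
            if j > i:  # each pairing once
                diags.setdefault(i + j, []).append(i)
    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    for c, ivals in diags.items():
        ivals.sort()
        run_start = prev = ivals[0]
        runs = []
        for i in ivals[1:]:
            if i == prev + 1:
                prev = i
                continue
            runs.append((run_start, prev))
            run_start = prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            length = b - a + k
            if length < min_ir:
                continue
            i1 = (a, a + length)
            i2 = (c - b, c - b + length)
            # normalize to circle coordinates, first copy start in [0, L)
            if i1[0] >= L:
                i1, i2 = (i1[0] - L, i1[1] - L), (i2[0] - L, i2[1] - L)
            if i2[0] >= L and i2[1] - L >= i1[1]:
                i2 = (i2[0] - L, i2[1] - L)
            lo, hi = sorted((i1, i2))
            if lo[1] > hi[0] or hi[1] - L > lo[0] or length > L // 2:
                continue  # copies overlap on the circle
            if best is None or length > best[0]:
                best = (length, lo, hi)
    if best is None:
        raise NoInvertedRepeatError(f"no inverted repeat >= {min_ir} bp found")
    _, i1, i2 = best
    arc_a = (i1[1], i2[0])                  # between copy 1 end and copy 2 start
    arc_b = (i2[1], i1[0] + L)              # wraps past the origin
    len_a, len_b = arc_a[1] - arc_a[0], arc_b[1] - arc_b[0]
    if len_a >= len_b:
        lsc, ssc = arc_a, arc_b
    else:
        lsc, ssc = arc_b, arc_a
    return (i1, i2), lsc, ssc


def _slice_circular(seq: str, interval: tuple[int, int]) -> str:
    s, e = interval
    L = len(seq)
    return (seq + seq)[s:e] if e > L else seq[s:e]


def extract_layout(asm: Assembly, min_ir: int = 1000) -> PlastomeLayout:
    """Annotate a circular assembly into LSC / IR / SSC."""
    if not asm.circular:
        raise ValueError("layout requires a circular assembly")
    seq = asm.scaffolds[0].sequence
    (i1, i2), lsc_iv, ssc_iv = find_inverted_repeat(seq, min_ir=min_ir)
    lsc = _slice_circular(seq, lsc_iv)
    ssc = _slice_circular(seq, ssc_iv)
    # the IR copy that follows the LSC (so that lsc+ir+ssc+rc(ir) rebuilds it)
    if lsc_iv[1] % len(seq) == i1[0] % len(seq):
        ir = _slice_circular(seq, i1)
    else:
        ir = _slice_circular(seq, i2)
    return PlastomeLayout(lsc=lsc, ir=ir, ssc=ssc)


def layout_outputs(asm: Assembly, mode: str, min_ir: int = 1000,
                   seed: int = 0) -> list[tuple[str, str]]:
    """Final outputs: FASTA-ready (name, sequence) records.

    ``three_linear``: LSC, IR, SSC fragments.  ``two_circular``: both SSC
    orientations.  ``one_circular``: one orientation chosen by seeded RNG.
    Headers carry 1-based inclusive coordinates.  Without a detectable IR
    only ``one_circular`` is permitted.
    """
    if not asm.circular:
        raise ValueError("layout requires a circular assembly")
    try:
        lay = extract_layout(asm, min_ir=min_ir)
    except NoInvertedRepeatError:
        if mode == "one_circular":
            return [("assembly circular=true", asm.scaffolds[0].sequence)]
        raise
    nl, ni, ns = len(lay.lsc), len(lay.ir), len(lay.ssc)
    if mode == "three_linear":
        return [
            (f"LSC:1-{nl}", lay.lsc),
            (f"IR:1-{ni}", lay.ir),
            (f"SSC:1-{ns}", lay.ssc),
        ]
    conf_a = lay.circular_sequence
    conf_b = PlastomeLayout(lay.lsc, lay.ir, revcomp(lay.ssc), "B").circular_sequence
    if mode == "two_circular":
        return [
            ("assembly_sscA circular=true", conf_a),
            ("assembly_sscB circular=true", conf_b),
        ]
    if mode == "one_circular":
        pick = np.random.default_rng(seed).integers(0, 2)
        name = "assembly_ssc" + ("A" if pick == 0 else "B")
        return [(name + " circular=true", conf_a if pick == 0 else conf_b)]
    raise ValueError(f"unknown layout mode {mode!r}")


# ---------------------------------------------------------------------------
# connectivity-matrix re-scaffolding


@dataclass
class ConnectivityMatrix:
    """Counts of read(-pair)s supporting a link between two scaffold ends."""

    counts: dict[tuple[End, End], int] = field(default_factory=dict)

    def add(self, end_a: End, end_b: End, n: int = 1) -> None:
        key = (end_a, end_b) if end_a <= end_b else (end_b, end_a)
        self.counts[key] = self.counts.get(key, 0) + n

    def get(self, end_a: End, end_b: End) -> int:
        key = (end_a, end_b) if end_a <= end_b else (end_b, end_a)
        return self.counts.get(key, 0)


def rescaffold_with_matrix(asm: Assembly, matrix: ConnectivityMatrix,
                           min_support: int = 3, gap_n: int = 100) -> Assembly:
    """Greedily join scaffold ends with enough spanning-read support.

    Highest support first, each end used at most once, inserting a run of
    ``gap_n`` N characters at each junction.  May close into a circular
    assembly.  Conflicting lower-ranked joins are skipped and logged.
    """
    seqs = [s.sequence for s in asm.scaffolds]
    chains = _ChainSet(seqs)
    items = [(n, ea, eb) for (ea, eb), n in matrix.counts.items() if n >= min_support]
    for n, ea, eb in sorted(items, key=lambda r: (-r[0], r[1], r[2])):
        if not chains.join(ea, eb, ("gap", gap_n)):
            logger.info("skipping conflicting join %s-%s (support %d)", ea, eb, n)
    spelled = chains.spell()
    spelled.sort(key=lambda sc: (-len(sc[0]), sc[0]))
    circular = len(spelled) == 1 and spelled[0][1]
    scaffolds = [Scaffold(f"r{i}", s) for i, (s, _) in enumerate(spelled)]
    return asm.replace_scaffolds(scaffolds, circular=circular)
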