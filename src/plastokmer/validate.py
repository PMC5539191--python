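"""Comparison of assemblies against a known circle.

Two circularizations of the same molecule differ by rotation, strand and —
for a plastome — the orientation of the SSC arc, none of which a short-read
assembly can resolve.  ``circular_identity`` therefore scores a candidate
against every equivalent form of the truth circle and reports the best
percent identity (edlib global alignment).
"""

from __future__ import annotations

import edlib

from .dna import revcomp


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    return 100.0 * (1.0 - res["editDistance"] / max(len(a), len(b)))


def rotations_equal(a: str, b: str) -> bool:
    """True if circles a and b are equal up to rotation and strand."""
    if len(a) != len(b):
        return False
    return a in b + b or revcomp(a) in b + b


def circular_identity(candidate: str, truth_circle: str,
                      ssc_variants: tuple[str, ...] = ()) -> float:
    """Best percent identity of ``candidate`` against all rotations/strands
    of the truth circle (and any alternative configurations supplied, e.g.
    the flipped-SSC plastome)."""
    best = 0.0
    for truth in (truth_circle, *ssc_variants):
        for t in (truth, revcomp(truth)):
            if rotations_equal(candidate, t):
                return 100.0
            doubled = t + t
            # align against the doubled circle to absorb rotation, using the
            # candidate as query in infix mode
            res = edlib.align(candidate, doubled, task="distance", mode="HW")
            if res["editDistance"] >= 0:
                ident = 100.0 * (1.0 - res["editDistance"] / len(candidate))
                # penalize length disagreement with the truth circle
                ident -= 100.0 * abs(len(candidate) - len(t)) / len(t)
                best = max(best, min(100.0, ident))
    return best


def plastome_variants(lsc: str, ir: str, ssc: str) -> tuple[str, tuple[str, ...]]:
    """The truth circle and its flipped-SSC configuration."""
    main = lsc + ir + ssc + revcomp(ir)
    flipped = lsc + ir + revcomp(ssc) + revcomp(ir)
    return main, (flipped,)
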