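"""Small DNA string helpers shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: byte -> 2-bit code; A=0, C=1, G=2, T=3 so that numeric order of encoded
#: k-mers equals lexicographic order of the strings. Anything else (N, ...) -> 255.
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    CODE[ord(_b)] = _i
    CODE[ord(_b.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (255 marks non-ACGT)."""
    return CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode_codes(codes: np.ndarray) -> str:
    """Turn a 0..3 code array back into a DNA string."""
    return _ASCII[codes].tobytes().decode("ascii")


def random_seq(length: int, rng: np.random.Generator) -> str:
    return decode_codes(rng.integers(0, 4, size=length, dtype=np.uint8))
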