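"""Nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> 2-bit code; N and anything unexpected -> 4 (matches nothing)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random ACGT string of length ``n``."""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def is_wc(a: str, b: str) -> bool:
    """Watson-Crick pair (DNA alphabet, T for U)."""
    return (a, b) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_gu(a: str, b: str) -> bool:
    """G:U wobble pair (written G:T in DNA space)."""
    return (a, b) in {("G", "T"), ("T", "G")}
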