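"""Low-level sequence codec shared across the package.

Bases are held as uint8 codes: A=0, C=1, G=2, T=3, N=4. Everything that is
performance-sensitive (simulation, mapping, window counting) works on code
arrays; strings only appear at the I/O boundary.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_CODE_TO_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)

_CHAR_TO_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CHAR_TO_CODE[_b] = _i
    _CHAR_TO_CODE[_b + 32] = _i  # lowercase


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into uint8 codes (unknown characters become N)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CHAR_TO_CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a 1-D uint8 code array back into a DNA string."""
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement (A<->T, C<->G); N stays N. Works on any shape."""
    return np.where(codes < 4, 3 - codes, np.uint8(N)).astype(np.uint8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return complement_codes(codes[..., ::-1])


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between equal-length code arrays; N mismatches everything."""
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    return int(((a != b) | (a == N) | (b == N)).sum())
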