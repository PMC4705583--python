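"""Low-level sequence encoding helpers.

Nucleotides are encoded as uint8 codes A=0, C=1, G=2, T=3, N=4.  The 2-bit
codes of A/C/G/T are chosen so that complementation is ``3 - code`` and so
that k-mers up to k=31 pack into a single int64.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (N and anything odd -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of `codes` into int64 (2 bits/base, k <= 31).

    K-mers containing N are reported as -1 so callers can drop them.
    """
    if k > 31:
        raise ValueError("k must be <= 31 to fit in int64")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    bad = c >= 4
    c[bad] = 0
    vals = np.zeros(n, dtype=np.int64)
    for j in range(k):
        vals = (vals << 2) | c[j : j + n]
    # mark k-mers overlapping an N
    if bad.any():
        w = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid")
        vals[w > 0] = -1
    return vals


def left_align_indel(seq_at, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Shift an anchored insertion/deletion to its leftmost equivalent form.

    ``seq_at(i)`` returns the reference base at position i.  Standard VCF
    normalization: while the trailing bases of ref and alt agree, rotate
    the event one base left.  Returns (pos, ref, alt) in canonical form.
    """
    while pos > 0 and ref[-1] == alt[-1]:
        prev = seq_at(pos - 1)
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return pos, ref, alt


def is_transition(a: str, b: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    return (a in PURINES) == (b in PURINES) and a != b
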