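"""Nucleotide codes shared across the package.

Alleles are stored as small integers (A=0, C=1, G=2, T=3). Two sentinel
codes mark drone observations that are not a clean haploid base call:
``MISSING`` (no call) and ``HET`` (a heterozygous call in a haploid drone,
expected only inside multi-copy regions or as a genotyping artifact).
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
MISSING = np.int8(-1)
HET = np.int8(-2)

NUCLEOTIDES = "ACGT"
_CODE = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: codes for G and C, used by GC-bias statistics
GC_CODES = frozenset({C, G})


def encode_base(base: str) -> np.int8:
    """Encode a single nucleotide letter as its int8 code."""
    try:
        return np.int8(_CODE[base.upper()])
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


def decode_base(code: int) -> str:
    """Decode an int8 allele code back to a letter ('.' for sentinels)."""
    return NUCLEOTIDES[code] if 0 <= code <= 3 else "."


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes; non-ACGT (N, gaps) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, MISSING, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_sequence(codes: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGTN", dtype=np.uint8)
    idx = np.where((codes >= 0) & (codes <= 3), codes, 4).astype(np.intp)
    return lookup[idx].tobytes().decode("ascii")


def is_gc(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of codes that are G or C."""
    return (codes == C) | (codes == G)
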