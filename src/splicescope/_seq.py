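"""Low-level nucleotide sequence helpers shared across modules.

Sequences are handled in two forms: plain upper-case strings for I/O and
small windows, and ``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3, N=4)
for bulk comparison work in the aligner.
"""
from __future__ import annotations

import numpy as np

NUCS = "ACGT"
NUC_TO_CODE = {c: i for i, c in enumerate("ACGTN")}
CODE_TO_NUC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level translation table: code of the complement base
_COMP_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _c, _i in NUC_TO_CODE.items():
    _ENCODE_TABLE[ord(_c)] = _i
    _ENCODE_TABLE[ord(_c.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (N and anything
    unrecognized map to code 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


def decode(codes: np.ndarray) -> str:
    return CODE_TO_NUC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODES[codes][::-1]
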