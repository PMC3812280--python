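"""Low-level sequence helpers shared across modules.

Bases are kept as Python strings at module interfaces and as uint8 code
arrays (A=0, C=1, G=2, T=3; U=4, N=5) for vectorised counting.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T, U, N = 0, 1, 2, 3, 4, 5

#: byte value -> base code lookup (everything unexpected maps to N)
_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGTU"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: code -> complementary code (U complements to A like T; N stays N)
_COMP_CODE = np.array([T, G, C, A, A, N], dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a sequence string."""
    lut = np.frombuffer(b"ACGTUN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)


def revcomp(seq: str) -> str:
    """Reverse complement; U complements to A (it pairs like T)."""
    return seq.translate(_COMP_TABLE)[::-1]


def comp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes]


def base_fractions(codes: np.ndarray) -> np.ndarray:
    """Fractions of A, C, G, T in a code array (ignores U/N)."""
    counts = np.bincount(codes, minlength=6)[:4].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sequence")
    return counts / total
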