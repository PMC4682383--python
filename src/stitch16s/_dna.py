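"""Low-level DNA utilities: IUPAC codes, reverse complement, 2-bit encoding.

All sequence handling in the package assumes upper-case DNA over {A,C,G,T,N}
for reads/references; primers may additionally carry IUPAC degeneracy codes.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)

# 4-bit base masks: bit per concrete base, A=1 C=2 G=4 T=8.  Two codes are
# compatible iff their masks intersect.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

_MASK_LUT = np.zeros(128, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m

# 2-bit encoding for k-mer hashing; N and degenerate codes map to 255.
_TWOBIT_LUT = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _TWOBIT_LUT[ord(_c)] = _i
    _TWOBIT_LUT[ord(_c.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def mask_array(seq: str) -> np.ndarray:
    """IUPAC compatibility masks for a sequence (uint8 array)."""
    return _MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def twobit_array(seq: str) -> np.ndarray:
    """2-bit codes (255 for non-ACGT)."""
    return _TWOBIT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; k-mers touching non-ACGT bases get -1.

    Rolling 2-bit packing; returns an int64 array of length len(seq)-k+1
    (empty if the sequence is shorter than k).
    """
    enc = twobit_array(seq).astype(np.int64)
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = enc == 255
    enc = np.where(bad, 0, enc)
    code = np.zeros(n, dtype=np.int64)
    for i in range(k):
        code = (code << 2) | enc[i : i + n]
    # invalidate windows containing any bad base
    badwin = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64))[
        k - 1 : k - 1 + n
    ]
    code[badwin > 0] = -1
    return code


def matches_iupac(primer: str, window: str) -> bool:
    """True if every primer position is compatible with the window base."""
    if len(primer) != len(window):
        return False
    pm = mask_array(primer)
    wm = mask_array(window)
    return bool(np.all(pm & wm))


def hamming_iupac(primer: str, window: str) -> int:
    """Number of incompatible positions between primer and same-length window."""
    pm = mask_array(primer)
    wm = mask_array(window)
    return int(np.sum((pm & wm) == 0))
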