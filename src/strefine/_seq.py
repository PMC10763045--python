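"""Nucleotide sequence utilities: encodings, IUPAC handling, reverse complement.

Two encodings are used throughout:

* ``code2`` — 0..3 for A,C,G,T, 4 for anything ambiguous. Used for exact
  k-mer hashing (ambiguous positions never seed).
* ``mask4`` — 4-bit IUPAC bitmask (A=1, C=2, G=4, T=8). Two bases are
  *compatible* when their masks intersect; this is how IUPAC codes emitted
  by the consensus caller keep matching reads in later iterations.
"""

from __future__ import annotations

import numpy as np

IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
MASK_IUPAC = {v: k for k, v in IUPAC_MASK.items()}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

VALID_BASES = frozenset(IUPAC_MASK)

# lookup tables indexed by byte value of an uppercase ASCII base
_CODE2_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE2_LUT[ord(_b)] = _i
_MASK4_LUT = np.zeros(256, dtype=np.uint8)
for _b, _m in IUPAC_MASK.items():
    _MASK4_LUT[ord(_b)] = _m

_COMP_MASK_LUT = np.zeros(16, dtype=np.uint8)
for _m in range(1, 16):
    _rc = 0
    for _bit, _cbit in ((1, 8), (2, 4), (4, 2), (8, 1)):
        if _m & _bit:
            _rc |= _cbit
    _COMP_MASK_LUT[_m] = _rc


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMP)[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def encode_code2(seq: str) -> np.ndarray:
    """2-bit-style codes: 0..3 for ACGT, 4 for ambiguity."""
    return _CODE2_LUT[seq_to_bytes(seq)]


def encode_mask4(seq: str) -> np.ndarray:
    """4-bit IUPAC bitmasks (0 for characters outside the alphabet)."""
    return _MASK4_LUT[seq_to_bytes(seq)]


def revcomp_mask4(mask: np.ndarray) -> np.ndarray:
    return _COMP_MASK_LUT[mask][::-1]


def compatible(a: str, b: str) -> bool:
    """True when two IUPAC bases can denote the same nucleotide."""
    return bool(IUPAC_MASK.get(a, 0) & IUPAC_MASK.get(b, 0))


def seqs_compatible(a: str, b: str) -> bool:
    """Length-equal, position-wise IUPAC-compatible comparison."""
    if len(a) != len(b):
        return False
    if a == b:
        return True
    ma = encode_mask4(a)
    mb = encode_mask4(b)
    return bool(np.all(ma & mb))


def iupac_from_bases(bases) -> str:
    """Single IUPAC code covering a set of concrete bases."""
    m = 0
    for b in bases:
        m |= IUPAC_MASK[b]
    return MASK_IUPAC[m]


def validate_sequence(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)!r}")
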