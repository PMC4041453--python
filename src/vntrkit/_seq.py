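"""Shared low-level sequence utilities (encoding, complement, IUPAC handling)."""

from __future__ import annotations

import re

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtnRYSWKMBDHVryswkmbdhv", "TGCANtgcanYRSWMKVHDByrswmkvhdb")

#: IUPAC nucleotide codes -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# byte codes: A=0 C=1 G=2 T=3, anything else (N etc.) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into a regex over A/C/G/T text."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def iupac_allowed_matrix(pattern: str) -> np.ndarray:
    """Boolean (len(pattern), 5) matrix: allowed[i, code] for codes A,C,G,T,N."""
    out = np.zeros((len(pattern), 5), dtype=bool)
    for i, ch in enumerate(pattern.upper()):
        if ch not in IUPAC:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        for b in IUPAC[ch]:
            out[i, BASES.index(b)] = True
    return out


def is_palindromic(pattern: str) -> bool:
    """True if the IUPAC site equals its own reverse complement."""
    return pattern.upper() == revcomp(pattern.upper())


def validate_dna(seq: str, name: str = "sequence") -> None:
    if not isinstance(seq, str):
        raise TypeError(f"{name} must be a string")
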