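"""Small DNA utilities shared across the package.

Sequences are uppercase strings over the alphabet A, C, G, T, N.  All
coordinates handled here are 1-based inclusive, matching the GFF
convention used at every external interface.
"""

from __future__ import annotations

import numpy as np

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level encoding: A,C,G,T -> 0..3, anything else -> 4 (treated as N)
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, N/other=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_has_internal_stop(cds: str) -> bool:
    """True if any codon before the last one is a stop codon."""
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return True
    return False
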