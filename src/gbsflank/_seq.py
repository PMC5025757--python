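"""Small shared DNA-sequence helpers."""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: index used for any letter outside A/C/G/T (scored as -inf by the scanner)
N_IDX = 4


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N and case preserved)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into ``BASES``; non-ACGT -> N_IDX."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, N_IDX, dtype=np.int8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def decode(idx) -> str:
    return "".join(BASES[i] if 0 <= i < 4 else "N" for i in idx)


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return sum(c in "GC" for c in s) / len(s) if s else float("nan")
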