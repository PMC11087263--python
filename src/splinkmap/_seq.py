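"""Small DNA-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

TTAA = "TTAA"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code used by the aligner and simulator
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array of 2-bit codes."""
    arr = _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _CODE_TO_BASE[arr].tobytes().decode("ascii")


def find_motif(seq: str, motif: str = TTAA) -> list[int]:
    """All (overlapping) start positions of *motif* in *seq*."""
    hits: list[int] = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def validate_dna(seq: str, name: str = "sequence") -> str:
    s = seq.upper()
    if not s or set(s) - set("ACGT"):
        raise ValueError(f"{name} must be non-empty A/C/G/T, got {seq!r}")
    return s
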