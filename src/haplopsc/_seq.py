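"""Base encoding helpers: sequences are numpy uint8 arrays over codes 0..3 (ACGT)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 code array. Raises on non-ACGT characters."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set(BASES + BASES.lower()))
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    """uint8 code array -> ACGT string."""
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    if a.shape != b.shape:
        raise ValueError("hamming requires equal-length sequences")
    return int((a != b).sum())


def identity_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Pairwise identity over the aligned overlap, divided by the shorter length.

    Sequences are compared at offset zero (the simulator's alleles and paralogs
    are positionally homologous; isoforms are interval slices).
    """
    m = min(len(a), len(b))
    if m == 0:
        raise ValueError("empty sequence")
    return float((a[:m] == b[:m]).sum()) / m
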