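"""Internal base/codon integer encodings shared by the counting and Markov engines.

Bases map A=0, C=1, G=2, T=3; a triplet encodes to 16*b0 + 4*b1 + b2, so codon
indices 0..63 enumerate codons in lexicographic ACGT order.
"""
from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"
N_CODONS = 64

#: all 64 codons in index order (index i decodes CODONS[i])
CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(BASES):
    _LUT[ord(_ch)] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 array; raise on any other character."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    out = _LUT[raw]
    if out.size and out.max() > 3:
        bad = chr(raw[int(np.argmax(out > 3))])
        raise InvalidSequenceError(f"invalid base {bad!r} in sequence")
    return out


def decode_seq(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def is_valid_seq(seq: str) -> bool:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return bool((_LUT[raw] <= 3).all()) if raw.size else True


def triplet_codes(arr: np.ndarray) -> np.ndarray:
    """Codes of all overlapping triplets; length len(arr) - 2 (empty if shorter)."""
    if arr.size < 3:
        return np.empty(0, dtype=np.int16)
    a = arr.astype(np.int16)
    return a[:-2] * 16 + a[1:-1] * 4 + a[2:]


def codon_index(codon: str) -> int:
    try:
        return CODON_INDEX[codon]
    except KeyError:
        raise InvalidSequenceError(f"not a valid codon: {codon!r}") from None
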