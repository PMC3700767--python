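"""Counting codon occurrences in the +1 and +2 reading frames.

Frames are defined on 0-based positions: the +1 frame scans triplets starting
at positions ≡ 1 (mod 3), the +2 frame at positions ≡ 2 (mod 3).  Every such
triplet spans the junction of two consecutive in-frame codons; counts never
cross transcript boundaries, incomplete trailing triplets are ignored, and
in-frame (phase-0) occurrences are never counted here.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._encode import InvalidSequenceError, encode_seq, triplet_codes, codon_index
from .genetic_code import DEFAULT_STOPS, validate_codon
from .transcripts import Transcriptome

#: name accepted anywhere a target set is, meaning the pooled default stop set
ALL_STOPS = "ALL_STOPS"

TargetSpec = "str | Iterable[str]"


def resolve_targets(targets) -> tuple[str, frozenset[str]]:
    """Normalize a target spec (codon, ALL_STOPS, or iterable) to (label, set)."""
    if isinstance(targets, str):
        if targets == ALL_STOPS:
            return ALL_STOPS, DEFAULT_STOPS
        return validate_codon(targets), frozenset({targets})
    tset = frozenset(validate_codon(c) for c in targets)
    if not tset:
        raise ValueError("empty target set")
    label = ALL_STOPS if tset == DEFAULT_STOPS else "+".join(sorted(tset))
    return label, tset


@dataclass(frozen=True)
class OffFrameCounts:
    target: str
    count_plus1: int
    count_plus2: int

    @property
    def total(self) -> int:
        return self.count_plus1 + self.count_plus2

    def __add__(self, other: "OffFrameCounts") -> "OffFrameCounts":
        if self.target != other.target:
            raise ValueError("cannot add counts for different targets")
        return OffFrameCounts(
            self.target,
            self.count_plus1 + other.count_plus1,
            self.count_plus2 + other.count_plus2,
        )


def count64_by_frame(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of all 64 triplets in the +1 and +2 frames of one encoded sequence."""
    codes = triplet_codes(arr)
    plus1 = np.bincount(codes[1::3], minlength=64)
    plus2 = np.bincount(codes[2::3], minlength=64)
    return plus1, plus2


def count_offframe(seq: str, targets) -> OffFrameCounts:
    """Count off-frame occurrences of the target codon(s) in one sequence."""
    label, tset = resolve_targets(targets)
    arr = encode_seq(seq)
    if arr.size < 3:
        return OffFrameCounts(label, 0, 0)
    plus1, plus2 = count64_by_frame(arr)
    idx = [codon_index(c) for c in tset]
    return OffFrameCounts(label, int(plus1[idx].sum()), int(plus2[idx].sum()))


def count_transcriptome(t: Transcriptome, targets) -> OffFrameCounts:
    """Element-wise sum of per-transcript off-frame counts (boundaries respected)."""
    label, tset = resolve_targets(targets)
    idx = [codon_index(c) for c in tset]
    p1, p2 = count64_transcriptome(t)
    return OffFrameCounts(label, int(p1[idx].sum()), int(p2[idx].sum()))


def count64_transcriptome(t: Transcriptome) -> tuple[np.ndarray, np.ndarray]:
    """All-64-codon off-frame counts for a transcriptome, per frame."""
    plus1 = np.zeros(64, dtype=np.int64)
    plus2 = np.zeros(64, dtype=np.int64)
    for tr in t.transcripts:
        arr = encode_seq(tr.seq)
        if arr.size < 3:
            continue
        a, b = count64_by_frame(arr)
        plus1 += a
        plus2 += b
    return plus1, plus2
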