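"""Standard genetic code and the off-frame stop (OSC) potential of each codon.

An off-frame stop codon (OSC, also called a hidden stop) is a stop triplet read
in the +1 or +2 frame of a coding sequence; it always spans the junction of two
consecutive in-frame codons.  A given sense codon can complete an OSC with a
suitable neighbor in between zero and six distinct ways, counting a "way" as a
distinct (stop codon, junction offset) completion with a free neighbor on
either side.  AGT reaches the maximum of six.  (The figure that popularized
this enumeration labels AGT an arginine codon; AGT encodes serine in the
standard code — the count of six is unaffected.)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._encode import BASES, CODONS, InvalidSequenceError

DEFAULT_STOPS = frozenset({"TAA", "TAG", "TGA"})

# standard (translation table 1) code, codons in ACGT lexicographic order
_STANDARD_AA = (
    "KNKNTTTTRSRSIIMI"  # AAA..ATT block (A**)
    "QHQHPPPPRRRRLLLL"  # C**
    "EDEDAAAAGGGGVVVV"  # G**
    "*Y*YSSSS*CWCLFLF"  # T**
)
STANDARD_TABLE: dict[str, str] = {c: aa for c, aa in zip(CODONS, _STANDARD_AA)}


def validate_codon(codon: str) -> str:
    """Return the codon unchanged if it is a 3-letter ACGT string; else raise."""
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in BASES for b in codon):
        raise InvalidSequenceError(f"not a valid codon: {codon!r}")
    return codon


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid table (64 entries) plus the set of stop codons.

    Only the standard nuclear code ships as a default; organisms that reassign
    stop codons must be handled by passing an explicit table and are otherwise
    the caller's responsibility to exclude.
    """

    table: dict[str, str] = field(default_factory=lambda: dict(STANDARD_TABLE))
    stops: frozenset[str] = DEFAULT_STOPS

    def __post_init__(self) -> None:
        if len(self.table) != 64 or set(self.table) != set(CODONS):
            raise ValueError("genetic code table must have exactly the 64 codons as keys")
        if not self.stops:
            raise ValueError("stop set must be non-empty")
        if not set(self.stops) <= set(self.table):
            raise ValueError("stops must be a subset of the table keys")
        object.__setattr__(self, "stops", frozenset(self.stops))

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls()

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The sense codons (61 under the standard code), in ACGT order."""
        return tuple(c for c in CODONS if c not in self.stops)


def osc_potential(codon: str, stops: frozenset[str] | set[str] = DEFAULT_STOPS) -> int:
    """Number of distinct (stop, junction-offset) ways ``codon`` can form an OSC.

    With a free neighbor on either side there are four completing slots: the
    codon's last two bases start a stop (+1 on the right junction), its last
    base starts a stop (+2 right), its first base ends a stop (+1 left), and
    its first two bases end a stop (+2 left).

    Ranges 0..6 for the standard stop set.
    """
    validate_codon(codon)
    if not stops:
        raise ValueError("stop set must be non-empty")
    for s in stops:
        validate_codon(s)
    n = 0
    for s in stops:
        n += s[:2] == codon[1:]   # s1 s2 == c2 c3
        n += s[0] == codon[2]     # s1 == c3
        n += s[2] == codon[0]     # s3 == c1
        n += s[1:] == codon[:2]   # s2 s3 == c1 c2
    return n


def potential_table(code: GeneticCode | None = None) -> dict[str, int]:
    """OSC potential for all 64 codons of ``code`` (default: standard)."""
    if code is None:
        code = GeneticCode.standard()
    return {c: osc_potential(c, code.stops) for c in CODONS}


def write_potential_table(path: str | Path, code: GeneticCode | None = None) -> None:
    """Export the potential table as TSV with columns codon, amino_acid, ways."""
    if code is None:
        code = GeneticCode.standard()
    table = potential_table(code)
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tways\n")
        for c in CODONS:
            fh.write(f"{c}\t{code.table[c]}\t{table[c]}\n")
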