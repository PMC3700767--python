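"""Reading, filtering, and summarizing per-organism CDS collections.

Inputs are coding-strand, frame-0 nucleotide FASTA files (one record per
transcript).  Filtering drops transcripts whose length is not a multiple of
three, that contain any non-ACGT character, or that contain an internal
in-frame stop; a single terminal in-frame stop codon is then stripped so the
retained sequences are entirely stop-free in frame.  Observed off-frame
counting and Markov training both operate on these identical filtered
sequences, so no constant length bias enters the observed/expected comparison.

No minimum-length cutoff is applied: every complete, unambiguous CDS counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._encode import encode_seq, is_valid_seq, triplet_codes, codon_index, CODONS
from .genetic_code import GeneticCode


@dataclass(frozen=True)
class Transcript:
    id: str
    seq: str


@dataclass
class Transcriptome:
    """An organism's ordered CDS collection."""

    organism_id: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def total_bases(self) -> int:
        return sum(len(t.seq) for t in self.transcripts)

    @property
    def n_codons(self) -> int:
        return self.total_bases // 3


@dataclass
class FilterReport:
    organism_id: str
    n_input: int = 0
    n_kept: int = 0
    n_dropped_length: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_internal_stop: int = 0

    TSV_COLUMNS = (
        "organism_id",
        "n_input",
        "n_kept",
        "n_dropped_length",
        "n_dropped_ambiguous",
        "n_dropped_internal_stop",
    )

    def as_row(self) -> tuple:
        return tuple(getattr(self, c) for c in self.TSV_COLUMNS)


class InputError(ValueError):
    """Unreadable, empty, or malformed input file."""


def read_cds_fasta(path: str | Path, organism_id: str | None = None) -> Transcriptome:
    """Read a CDS FASTA into an (unfiltered) Transcriptome.

    Sequences are upper-cased and RNA U is mapped to T; record order is
    preserved.  Raises InputError for a missing or empty file.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if organism_id is None:
        organism_id = path.stem
    transcripts = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            transcripts.append(Transcript(id=rec.id, seq=seq))
    except (ValueError, OSError) as exc:
        raise InputError(f"could not parse FASTA {path}: {exc}") from exc
    if not transcripts:
        raise InputError(f"no FASTA records in {path}")
    return Transcriptome(organism_id=organism_id, transcripts=transcripts)


def filter_transcripts(
    t: Transcriptome, code: GeneticCode | None = None
) -> tuple[Transcriptome, FilterReport]:
    """Apply CDS completeness filters and strip one terminal stop codon.

    A transcript is kept iff its length is divisible by 3, it contains only
    A/C/G/T, and no codon before the last one is a stop.  If the last codon is
    a stop it is removed.  Transcripts that become empty after stripping are
    dropped (counted under the length reason).  Idempotent.
    """
    if code is None:
        code = GeneticCode.standard()
    stops = code.stops
    report = FilterReport(organism_id=t.organism_id, n_input=len(t.transcripts))
    kept: list[Transcript] = []
    for tr in t.transcripts:
        seq = tr.seq
        if len(seq) % 3 != 0:
            report.n_dropped_length += 1
            continue
        if not is_valid_seq(seq):
            report.n_dropped_ambiguous += 1
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if any(c in stops for c in codons[:-1]):
            report.n_dropped_internal_stop += 1
            continue
        if codons and codons[-1] in stops:
            seq = seq[:-3]
        if not seq:
            report.n_dropped_length += 1
            continue
        kept.append(Transcript(id=tr.id, seq=seq))
    report.n_kept = len(kept)
    return Transcriptome(organism_id=t.organism_id, transcripts=kept), report


def codon_usage(t: Transcriptome, code: GeneticCode | None = None) -> dict[str, float]:
    """Relative in-frame codon frequencies pooled over all transcripts.

    Stop codons are excluded; values are normalized to sum to 1 over the 61
    sense codons.  Requires a filtered, non-empty transcriptome.
    """
    if code is None:
        code = GeneticCode.standard()
    if not t.transcripts or t.total_bases == 0:
        raise ValueError(f"empty transcriptome: {t.organism_id}")
    counts = np.zeros(64, dtype=np.int64)
    for tr in t.transcripts:
        arr = encode_seq(tr.seq)
        if arr.size < 3:
            continue
        codes = triplet_codes(arr)[::3]  # in-frame codons
        counts += np.bincount(codes, minlength=64)
    sense_idx = [codon_index(c) for c in code.sense_codons]
    total = counts[sense_idx].sum()
    if total == 0:
        raise ValueError(f"no sense codons in transcriptome: {t.organism_id}")
    return {CODONS[i]: counts[i] / total for i in sense_idx}


def gc_content(t: Transcriptome) -> float:
    """(G + C) / total bases pooled over all transcripts."""
    if not t.transcripts or t.total_bases == 0:
        raise ValueError(f"empty transcriptome: {t.organism_id}")
    gc = total = 0
    for tr in t.transcripts:
        arr = encode_seq(tr.seq)
        gc += int(((arr == 1) | (arr == 2)).sum())
        total += arr.size
    return gc / total


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Read a manifest TSV with (at least) columns organism_id and fasta_path.

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such manifest: {path}")
    rows: list[tuple[str, Path]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_org = header.index("organism_id")
            i_fa = header.index("fasta_path")
        except ValueError as exc:
            raise InputError(f"manifest must have organism_id and fasta_path columns: {path}") from exc
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            fa = Path(parts[i_fa])
            if not fa.is_absolute():
                fa = path.parent / fa
            rows.append((parts[i_org], fa))
    if not rows:
        raise InputError(f"empty manifest: {path}")
    return rows
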