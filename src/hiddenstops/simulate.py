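"""Synthetic transcriptomes with controllable GC content and off-frame enrichment.

The generator emulates the statistical structure the off-frame analyses
assume, not any particular species:

* GC content drives codon usage through an independent-base law — P(G) = P(C)
  = gc/2, P(A) = P(T) = (1-gc)/2 — with codon probability the product over its
  three bases, stop codons removed, renormalized over the 61 sense codons.
* Codons are sampled i.i.d. from that usage (delta = 0), giving an exact null
  for the excess pipeline: the dicodon distribution factorizes.
* Optional dicodon-level injection: while appending codon c after codon p, the
  proposal weight of c is multiplied by (1 + delta) whenever the junction
  creates at least one off-frame occurrence of the target codon (triplets
  p2p3c1 or p3c1c2).  Sequential proposal reweighting is exact — no rejection
  loops — so the achieved enrichment has a computable oracle.
* Optional terminal stop codon, drawn among the three stops proportionally to
  the same base law (then stripped again by the standard filters).

In-frame stops never occur in the body by construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._encode import BASES
from .genetic_code import DEFAULT_STOPS, GeneticCode, validate_codon
from .transcripts import Transcript, Transcriptome

#: deterministic master-seed → per-organism seed schedule (documented contract)
_SEED_MULT = 1_000_003
_SEED_STEP = 7_919
_SEED_MOD = 2**31 - 1


def derive_seed(master_seed: int, index: int) -> int:
    """Per-organism seed i = (master*1000003 + 7919*(i+1)) mod (2^31 - 1)."""
    return (master_seed * _SEED_MULT + _SEED_STEP * (index + 1)) % _SEED_MOD


@dataclass(frozen=True)
class SyntheticSpec:
    organism_id: str
    gc_target: float = 0.5
    n_transcripts: int = 100
    length_codons: int | tuple[int, int] = 300  # fixed, or (mean, min) geometric
    injection: tuple[str, float] | None = None  # (target codon, delta > -1)
    append_terminal_stop: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be strictly between 0 and 1")
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")
        if isinstance(self.length_codons, int):
            if self.length_codons < 2:
                raise ValueError("transcripts must be at least 2 codons long")
        else:
            mean, lo = self.length_codons
            if lo < 2 or mean < lo:
                raise ValueError("length distribution needs min >= 2 and mean >= min")
        if self.injection is not None:
            target, delta = self.injection
            validate_codon(target)
            if delta <= -1:
                raise ValueError("injection delta must be > -1")


def gc_driven_usage(gc: float, code: GeneticCode | None = None) -> dict[str, float]:
    """Sense-codon law implied by independent bases at the given GC fraction."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    if code is None:
        code = GeneticCode.standard()
    p_base = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    raw = {c: p_base[c[0]] * p_base[c[1]] * p_base[c[2]] for c in code.sense_codons}
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def junction_hits(sense: tuple[str, ...], target: str) -> np.ndarray:
    """hits[i, j] = 1 if appending sense[j] after sense[i] creates an off-frame
    occurrence of ``target`` at the junction (triplets p2p3c1 or p3c1c2)."""
    n = len(sense)
    hits = np.zeros((n, n), dtype=bool)
    for i, p in enumerate(sense):
        for j, c in enumerate(sense):
            hits[i, j] = (p[1:] + c[0] == target) or (p[2] + c[:2] == target)
    return hits


def _codon_bases(sense: tuple[str, ...]) -> np.ndarray:
    lut = {b: i for i, b in enumerate(BASES)}
    return np.array([[lut[b] for b in c] for c in sense], dtype=np.uint8)


def _sample_lengths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.length_codons, int):
        return np.full(spec.n_transcripts, spec.length_codons, dtype=np.int64)
    mean, lo = spec.length_codons
    p = 1.0 / (mean - lo + 1)
    return lo + rng.geometric(p, size=spec.n_transcripts) - 1


def generate_organism(spec: SyntheticSpec, code: GeneticCode | None = None) -> Transcriptome:
    """Sample one synthetic transcriptome according to ``spec`` (deterministic per seed)."""
    if code is None:
        code = GeneticCode.standard()
    rng = np.random.default_rng(spec.seed)
    sense = code.sense_codons
    usage = gc_driven_usage(spec.gc_target, code)
    u = np.array([usage[c] for c in sense])
    if spec.injection is not None:
        target, delta = spec.injection
        weights = u[None, :] * (1.0 + delta * junction_hits(sense, target))
        trans = weights / weights.sum(axis=1, keepdims=True)
    else:
        trans = np.tile(u, (len(sense), 1))
    cum_trans = np.cumsum(trans, axis=1)
    cum_trans[:, -1] = 1.0
    cum_init = np.cumsum(u)
    cum_init[-1] = 1.0

    lengths = _sample_lengths(spec, rng)
    T, lmax = spec.n_transcripts, int(lengths.max())
    out = np.empty((T, lmax), dtype=np.int64)
    states = np.searchsorted(cum_init, rng.random(T), side="right")
    out[:, 0] = states
    for pos in range(1, lmax):
        rows = cum_trans[states]
        u_draw = rng.random(T)
        states = (rows[:, :-1] <= u_draw[:, None]).sum(axis=1)
        out[:, pos] = states

    bases = _codon_bases(sense)
    stop_codons = sorted(DEFAULT_STOPS & set(code.stops)) or sorted(code.stops)
    if spec.append_terminal_stop:
        p_base = {"A": (1 - spec.gc_target) / 2, "T": (1 - spec.gc_target) / 2,
                  "G": spec.gc_target / 2, "C": spec.gc_target / 2}
        w = np.array([p_base[s[0]] * p_base[s[1]] * p_base[s[2]] for s in stop_codons])
        stop_draws = rng.choice(len(stop_codons), size=T, p=w / w.sum())

    transcripts = []
    decode = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for i in range(T):
        arr = bases[out[i, : lengths[i]]].reshape(-1)
        seq = decode[arr].tobytes().decode("ascii")
        if spec.append_terminal_stop:
            seq += stop_codons[stop_draws[i]]
        transcripts.append(Transcript(id=f"{spec.organism_id}_t{i:05d}", seq=seq))
    return Transcriptome(organism_id=spec.organism_id, transcripts=transcripts)


def generate_panel(
    gc_grid,
    master_seed: int = 0,
    n_transcripts: int = 100,
    length_codons: int | tuple[int, int] = 300,
    injection: tuple[str, float] | None = None,
    append_terminal_stop: bool = False,
    organism_prefix: str = "synth",
) -> list[tuple[SyntheticSpec, Transcriptome]]:
    """One organism per GC grid value, with per-organism seeds derived from the
    master seed by the documented schedule (reproducible piecewise)."""
    gc_grid = list(gc_grid)
    if not gc_grid:
        raise ValueError("empty GC grid")
    panel = []
    for i, gc in enumerate(gc_grid):
        spec = SyntheticSpec(
            organism_id=f"{organism_prefix}_{i:03d}_gc{gc:.3f}",
            gc_target=float(gc),
            n_transcripts=n_transcripts,
            length_codons=length_codons,
            injection=injection,
            append_terminal_stop=append_terminal_stop,
            seed=derive_seed(master_seed, i),
        )
        panel.append((spec, generate_organism(spec)))
    return panel


def write_fasta(t: Transcriptome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tr in t.transcripts:
            fh.write(f">{tr.id}\n")
            for i in range(0, len(tr.seq), width):
                fh.write(tr.seq[i : i + width] + "\n")


MANIFEST_COLUMNS = (
    "organism_id",
    "fasta_path",
    "gc_target",
    "seed",
    "n_transcripts",
    "length_codons",
    "injection_target",
    "injection_delta",
    "append_terminal_stop",
)


def write_manifest(rows: list[tuple[SyntheticSpec, str]], path: str | Path) -> None:
    """Write a manifest TSV of (spec, fasta_path) pairs consumable end-to-end."""
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for spec, fasta_path in rows:
            target, delta = spec.injection if spec.injection else ("", "")
            length = (
                spec.length_codons
                if isinstance(spec.length_codons, int)
                else f"{spec.length_codons[0]}:{spec.length_codons[1]}"
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        spec.organism_id,
                        fasta_path,
                        spec.gc_target,
                        spec.seed,
                        spec.n_transcripts,
                        length,
                        target,
                        delta,
                        int(spec.append_terminal_stop),
                    )
                )
                + "\n"
            )
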