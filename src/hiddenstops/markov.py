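"""Order-k, 3-periodic Markov models of coding sequence and replicate generation.

The null model for off-frame counting: an order-k Markov chain whose transition
law depends on the phase of the emitted base, phase = (0-based position) mod 3.
Trained on an organism's filtered transcriptome (terminal stops stripped), it
captures the phase-specific (k+1)-mer statistics — dinucleotide→base for k=2
("2-3 model"), pentanucleotide→base for k=5 ("5-3 model") — while scrambling
longer-range structure.  Randomized replicate transcriptomes are generated by
seeding each artificial transcript with the first k bases of its natural
counterpart and emitting bases from the trained law until the natural length is
reached, so transcript count and lengths are conserved exactly.

Because training uses no pseudocounts, a k=2 model trained on in-frame-stop-free
CDS assigns probability zero to every in-frame stop completion, and generated
replicates are in-frame-stop-free as well.

Contexts never observed at a phase (possible only via natural-prefix seeding)
back off to the longest observed suffix context, down to the phase-specific
base frequencies; fallback draws are counted and reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encode import BASES, decode_seq, encode_seq
from .transcripts import Transcript, Transcriptome

_CHUNK_ELEMENTS = 120_000_000  # max generated bases held in memory at once


@dataclass
class PeriodicMarkovModel:
    """Trained order-k, period-3 transition law.

    counts[p, ctx, b] tallies base b emitted at phase p after k-mer context
    ctx (lexicographic ACGT code); probs are the row-normalized counts where
    the context was seen at that phase.
    """

    k: int
    counts: np.ndarray  # (3, 4**k, 4) int64
    phase_base_counts: np.ndarray  # (3, 4) int64
    training_meta: dict = field(default_factory=dict)

    @property
    def seen(self) -> np.ndarray:
        return self.counts.sum(axis=-1) > 0

    @property
    def probs(self) -> np.ndarray:
        totals = self.counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / totals
        p[np.isnan(p)] = 0.0
        return p

    @property
    def phase_base_freqs(self) -> np.ndarray:
        return self.phase_base_counts / self.phase_base_counts.sum(axis=-1, keepdims=True)


@dataclass
class ReplicateSet:
    """Per-replicate all-64-codon off-frame counts for one organism and order."""

    n_replicates: int
    counts_plus1: np.ndarray  # (n_replicates, 64)
    counts_plus2: np.ndarray  # (n_replicates, 64)
    rng_seed: int | None = None
    fallback_draws: int = 0

    def totals_for(self, codon_indices) -> np.ndarray:
        """Pooled +1/+2 counts per replicate for a set of codon indices."""
        idx = list(codon_indices)
        return (self.counts_plus1[:, idx] + self.counts_plus2[:, idx]).sum(axis=1)


def train(t: Transcriptome, k: int) -> PeriodicMarkovModel:
    """Tally (phase, k-mer context, next base) transitions over a transcriptome.

    Contexts are confined within transcripts; positions 0..k-1 of each
    transcript contribute no transition (they seed generation instead).
    """
    if k < 1:
        raise ValueError("order k must be >= 1")
    if not t.transcripts or all(len(tr.seq) <= k for tr in t.transcripts):
        raise ValueError(f"transcriptome {t.organism_id} has no transcript longer than k={k}")
    nctx = 4**k
    flat = np.zeros(3 * nctx * 4, dtype=np.int64)
    phase_base = np.zeros(12, dtype=np.int64)
    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    for tr in t.transcripts:
        a = encode_seq(tr.seq)
        n = a.size
        if n == 0:
            continue
        phase_base += np.bincount((np.arange(n) % 3) * 4 + a, minlength=12)
        if n <= k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(a, k)[: n - k]
        ctx = windows.astype(np.int64) @ pows
        bases = a[k:]
        phases = np.arange(k, n, dtype=np.int64) % 3
        flat += np.bincount(phases * (nctx * 4) + ctx * 4 + bases, minlength=3 * nctx * 4)
    model = PeriodicMarkovModel(
        k=k,
        counts=flat.reshape(3, nctx, 4),
        phase_base_counts=phase_base.reshape(3, 4),
        training_meta={
            "organism_id": t.organism_id,
            "n_transcripts": len(t.transcripts),
            "total_bases": t.total_bases,
        },
    )
    return model


def _lower_order_counts(model: PeriodicMarkovModel, m: int) -> np.ndarray:
    """Aggregate order-k counts to order-m (< k) suffix-context counts."""
    k = model.k
    return model.counts.reshape(3, 4 ** (k - m), 4**m, 4).sum(axis=1)


@dataclass
class _Sampler:
    """Cumulative transition table with backoff-filled rows, ready to draw from."""

    k: int
    cum: np.ndarray  # (3, 4**k, 4) float64, last column == 1
    fallback_rows: np.ndarray  # (3, 4**k) bool


def build_sampler(model: PeriodicMarkovModel) -> _Sampler:
    k = model.k
    nctx = 4**k
    resolved = model.probs.copy()
    seen = model.seen
    fallback_rows = ~seen
    pbf = model.phase_base_freqs
    aggregates = {m: _lower_order_counts(model, m) for m in range(k - 1, 0, -1)}
    ctx_codes = np.arange(nctx, dtype=np.int64)
    for p in range(3):
        remaining = ctx_codes[~seen[p]]
        for m in range(k - 1, 0, -1):
            if remaining.size == 0:
                break
            suffix = remaining % (4**m)
            rows = aggregates[m][p, suffix]
            rowsum = rows.sum(axis=-1)
            ok = rowsum > 0
            if ok.any():
                resolved[p, remaining[ok]] = rows[ok] / rowsum[ok, None]
            remaining = remaining[~ok]
        if remaining.size:
            resolved[p, remaining] = pbf[p]
    cum = np.cumsum(resolved, axis=-1)
    cum[..., -1] = 1.0
    return _Sampler(k=k, cum=cum, fallback_rows=fallback_rows)


def _natural_matrix(t: Transcriptome) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(tr.seq) for tr in t.transcripts], dtype=np.int64)
    mat = np.zeros((len(lengths), int(lengths.max())), dtype=np.uint8)
    for i, tr in enumerate(t.transcripts):
        mat[i, : lengths[i]] = encode_seq(tr.seq)
    return mat, lengths


def _generate_block(
    sampler: _Sampler,
    nat_mat: np.ndarray,
    lengths: np.ndarray,
    reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Generate ``reps`` full replicate transcriptomes as one (reps*T, Lmax) block."""
    k = sampler.k
    T, lmax = nat_mat.shape
    R = reps * T
    out = np.empty((R, lmax), dtype=np.uint8)
    states = np.zeros(R, dtype=np.int64)
    mod = 4**k
    len_rows = np.tile(lengths, reps)
    any_fallback = sampler.fallback_rows.any(axis=1)
    fallback = 0
    for pos in range(lmax):
        if pos < k:
            base = np.tile(nat_mat[:, pos], reps)
        else:
            phase = pos % 3
            rows = sampler.cum[phase][states]
            u = rng.random(R)
            base = (rows[:, :3] <= u[:, None]).sum(axis=1).astype(np.uint8)
            if any_fallback[phase]:
                live = pos < len_rows
                if live.any():
                    fallback += int(sampler.fallback_rows[phase][states[live]].sum())
        out[:, pos] = base
        states = (states * 4 + base) % mod
    return out, fallback


def _count_block(
    out: np.ndarray, lengths: np.ndarray, reps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate 64-codon counts for frames +1 and +2 of a generated block."""
    R, lmax = out.shape
    T = R // reps
    a = out.astype(np.int16)
    codes = a[:, :-2] * 16 + a[:, 1:-1] * 4 + a[:, 2:]
    valid = np.arange(lmax - 2)[None, :] < (lengths - 2)[:, None]
    valid = np.tile(valid, (reps, 1))
    codes = np.where(valid, codes, 64)
    rep_ids = np.repeat(np.arange(reps, dtype=np.int64), T)
    res = []
    for frame in (1, 2):
        flat = codes[:, frame::3].astype(np.int64) + 65 * rep_ids[:, None]
        counts = np.bincount(flat.ravel(), minlength=65 * reps).reshape(reps, 65)
        res.append(counts[:, :64].astype(np.int64))
    return res[0], res[1]


def generate_transcript(
    model: PeriodicMarkovModel, natural: Transcript, rng: np.random.Generator
) -> Transcript:
    """One artificial transcript: natural k-base prefix, trained law thereafter,
    same length as the natural transcript."""
    sampler = build_sampler(model)
    nat = encode_seq(natural.seq)
    out, _ = _generate_block(
        sampler, nat[None, :], np.array([nat.size], dtype=np.int64), 1, rng
    )
    return Transcript(id=natural.id, seq=decode_seq(out[0]))


def generate_replicate_transcriptome(
    model: PeriodicMarkovModel, t: Transcriptome, rng: np.random.Generator
) -> Transcriptome:
    """One full randomized transcriptome (lengths conserved transcript-by-transcript)."""
    sampler = build_sampler(model)
    nat_mat, lengths = _natural_matrix(t)
    out, _ = _generate_block(sampler, nat_mat, lengths, 1, rng)
    transcripts = [
        Transcript(id=tr.id, seq=decode_seq(out[i, : lengths[i]]))
        for i, tr in enumerate(t.transcripts)
    ]
    return Transcriptome(organism_id=t.organism_id, transcripts=transcripts)


def generate_replicate_counts(
    model: PeriodicMarkovModel,
    t: Transcriptome,
    n: int = 200,
    rng: np.random.Generator | int | None = None,
) -> ReplicateSet:
    """Off-frame counts of all 64 codons in ``n`` randomized transcriptomes.

    One shared stream of replicates serves every per-codon analysis and the
    pooled-stop target simultaneously; replicate sequences are not retained.
    Deterministic for a fixed integer seed (or seeded Generator) and inputs.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sampler = build_sampler(model)
    nat_mat, lengths = _natural_matrix(t)
    T, lmax = nat_mat.shape
    reps_per_block = max(1, min(n, _CHUNK_ELEMENTS // max(1, T * lmax)))
    p1 = np.empty((n, 64), dtype=np.int64)
    p2 = np.empty((n, 64), dtype=np.int64)
    fallback = 0
    done = 0
    while done < n:
        reps = min(reps_per_block, n - done)
        block, fb = _generate_block(sampler, nat_mat, lengths, reps, rng)
        fallback += fb
        c1, c2 = _count_block(block, lengths, reps)
        p1[done : done + reps] = c1
        p2[done : done + reps] = c2
        done += reps
    return ReplicateSet(
        n_replicates=n,
        counts_plus1=p1,
        counts_plus2=p2,
        rng_seed=seed,
        fallback_draws=fallback,
    )


def write_model_tsv(model: PeriodicMarkovModel, path: str | Path) -> None:
    """Export as TSV: metadata header lines, then phase/context/base/count/probability."""
    probs = model.probs
    with open(path, "w") as fh:
        fh.write(f"# order\t{model.k}\n")
        for key, val in model.training_meta.items():
            fh.write(f"# {key}\t{val}\n")
        for p in range(3):
            fh.write(f"# phase_base_counts_{p}\t" + "\t".join(map(str, model.phase_base_counts[p])) + "\n")
        fh.write("phase\tcontext\tbase\tcount\tprobability\n")
        for p in range(3):
            for ctx in np.nonzero(model.seen[p])[0]:
                ctx_str = "".join(BASES[(ctx >> (2 * (model.k - 1 - j))) & 3] for j in range(model.k))
                for b in range(4):
                    c = model.counts[p, ctx, b]
                    if c:
                        fh.write(f"{p}\t{ctx_str}\t{BASES[b]}\t{c}\t{probs[p, ctx, b]:.10g}\n")


def read_model_tsv(path: str | Path) -> PeriodicMarkovModel:
    path = Path(path)
    k = None
    meta: dict = {}
    phase_base = np.zeros((3, 4), dtype=np.int64)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, *vals = line[1:].strip().split("\t")
                if key == "order":
                    k = int(vals[0])
                elif key.startswith("phase_base_counts_"):
                    phase_base[int(key[-1])] = [int(v) for v in vals]
                else:
                    meta[key] = vals[0] if vals else ""
            elif line and not line.startswith("phase\t"):
                rows.append(line.split("\t"))
    if k is None:
        raise ValueError(f"model file {path} lacks an order header")
    counts = np.zeros((3, 4**k, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for p, ctx_str, b, c, _prob in rows:
        ctx = 0
        for ch in ctx_str:
            ctx = ctx * 4 + base_idx[ch]
        counts[int(p), ctx, base_idx[b]] = int(c)
    return PeriodicMarkovModel(k=k, counts=counts, phase_base_counts=phase_base, training_meta=meta)
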