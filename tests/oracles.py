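"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (nested loops, enumeration, closed
forms, eigenvector stationary distributions) and shares no code with the
package's counting or sampling paths.
"""
from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"
ALL_CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
STOPS = ("TAA", "TAG", "TGA")


def osc_potential_oracle(codon: str, stops=STOPS) -> int:
    """Slide each stop across the two junction offsets of every ordered codon
    pair containing the focal codon; count distinct (stop, slot) completions."""
    ways = set()
    for neighbor in ALL_CODONS:
        left = neighbor + codon   # neighbor at i-1
        right = codon + neighbor  # neighbor at i+1
        for stop in stops:
            for off in (1, 2):
                if left[off : off + 3] == stop:
                    ways.add((stop, "left", off))
                if right[off : off + 3] == stop:
                    ways.add((stop, "right", off))
    return len(ways)


def count_offframe_oracle(seq: str, targets) -> tuple[int, int]:
    """Naive per-position scan of the +1/+2 frames of one sequence."""
    targets = set(targets)
    plus1 = plus2 = 0
    for i in range(len(seq) - 2):
        if i % 3 == 1 and seq[i : i + 3] in targets:
            plus1 += 1
        elif i % 3 == 2 and seq[i : i + 3] in targets:
            plus2 += 1
    return plus1, plus2


def count_concatenation_oracle(seqs, targets) -> int:
    """Scan the spacer-joined concatenation; 2-base 'X' spacers both break
    triplets across boundaries and preserve each sequence's phase (len % 3 == 0
    plus 2 spacer bases shifts phase by 2, but X never matches, and positions
    inside each sequence keep their own residue class relative to its start)."""
    targets = set(targets)
    total = 0
    offset = 0
    joined = ""
    starts = []
    for s in seqs:
        starts.append(len(joined))
        joined += s + "XX"
    for k, s in enumerate(seqs):
        for i in range(len(s) - 2):
            if i % 3 in (1, 2) and joined[starts[k] + i : starts[k] + i + 3] in targets:
                total += 1
    return total


def train_oracle(seqs, k: int):
    """Nested-loop tally of (phase, context, base) transition frequencies."""
    counts: dict[tuple[int, str, str], int] = {}
    for s in seqs:
        for i in range(k, len(s)):
            key = (i % 3, s[i - k : i], s[i])
            counts[key] = counts.get(key, 0) + 1
    probs: dict[tuple[int, str], dict[str, float]] = {}
    for (phase, ctx, b), n in counts.items():
        probs.setdefault((phase, ctx), {})[b] = n
    for key, row in probs.items():
        tot = sum(row.values())
        probs[key] = {b: n / tot for b, n in row.items()}
    return probs


def spearman_oracle(x, y) -> float:
    """Average-rank Spearman rho via the Pearson formula on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def ols_oracle(x, y) -> tuple[float, float]:
    """Normal-equations least squares: slope and intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.vstack([x, np.ones_like(x)]).T
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    return float(slope), float(intercept)


# --- exact injected-chain analysis ------------------------------------------

SENSE = [c for c in ALL_CODONS if c not in STOPS]


def _junction_count(p: str, c: str, target: str) -> int:
    return int(p[1:] + c[0] == target) + int(p[2] + c[:2] == target)


def injected_codon_chain(usage: dict[str, float], target: str, delta: float) -> np.ndarray:
    """Transition matrix over the 61 sense codons of the reweighted proposal chain."""
    n = len(SENSE)
    T = np.zeros((n, n))
    for i, p in enumerate(SENSE):
        w = np.array(
            [usage[c] * (1 + delta * (_junction_count(p, c, target) > 0)) for c in SENSE]
        )
        T[i] = w / w.sum()
    return T


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    v = np.real(vecs[:, np.argmin(abs(vals - 1))])
    v = np.abs(v)
    return v / v.sum()


def _hexamer_joint(pi: np.ndarray, T: np.ndarray, codons) -> np.ndarray:
    b = {ch: i for i, ch in enumerate(BASES)}
    joint = np.zeros((4,) * 6)
    for i, p in enumerate(codons):
        for j, c in enumerate(codons):
            joint[b[p[0]], b[p[1]], b[p[2]], b[c[0]], b[c[1]], b[c[2]]] += pi[i] * T[i, j]
    return joint


def _offframe_rate(pi: np.ndarray, T: np.ndarray, codons, target: str) -> float:
    """Expected off-frame occurrences of target per codon junction, stationary."""
    r = 0.0
    for i, p in enumerate(codons):
        for j, c in enumerate(codons):
            r += pi[i] * T[i, j] * _junction_count(p, c, target)
    return r


def _aggregated_codon_chain(joint: np.ndarray, k: int) -> np.ndarray:
    """64-codon chain implied by the order-k (k in {1,2}) 3-periodic aggregation
    of a stationary hexamer law."""
    b = {ch: i for i, ch in enumerate(BASES)}
    if k == 2:
        # contexts: phase0 (p1,p2); phase1 (p2,c0); phase2 (c0,c1)
        m0 = joint.sum(axis=(0, 4, 5))
        m1 = joint.sum(axis=(0, 1, 5))
        m2 = joint.sum(axis=(0, 1, 2))
        c0 = m0 / m0.sum(axis=2, keepdims=True)
        c1 = m1 / m1.sum(axis=2, keepdims=True)
        c2 = m2 / m2.sum(axis=2, keepdims=True)

        def trans(p, c):
            return (
                c0[b[p[1]], b[p[2]], b[c[0]]]
                * c1[b[p[2]], b[c[0]], b[c[1]]]
                * c2[b[c[0]], b[c[1]], b[c[2]]]
            )

    elif k == 1:
        m0 = joint.sum(axis=(0, 1, 4, 5))
        m1 = joint.sum(axis=(0, 1, 2, 5))
        m2 = joint.sum(axis=(0, 1, 2, 3))
        c0 = m0 / m0.sum(axis=1, keepdims=True)
        c1 = m1 / m1.sum(axis=1, keepdims=True)
        c2 = m2 / m2.sum(axis=1, keepdims=True)

        def trans(p, c):
            return c0[b[p[2]], b[c[0]]] * c1[b[c[0]], b[c[1]]] * c2[b[c[1]], b[c[2]]]

    else:
        raise ValueError("oracle supports k in {1, 2}")
    n = 64
    T = np.zeros((n, n))
    for i, p in enumerate(ALL_CODONS):
        for j, c in enumerate(ALL_CODONS):
            T[i, j] = trans(p, c)
    return T


def injection_log_ratio_oracle(
    usage: dict[str, float], target: str, delta: float, k_null: int
) -> float:
    """Exact expected log-ratio L(target) of the injected generator against an
    order-k 3-periodic null trained on its own output (infinite-data limit,
    edge effects ignored): ln(rate_true / rate_null)."""
    T = injected_codon_chain(usage, target, delta)
    pi = _stationary(T)
    rate_true = _offframe_rate(pi, T, SENSE, target)
    joint = _hexamer_joint(pi, T, SENSE)
    T_null = _aggregated_codon_chain(joint, k_null)
    pi_null = _stationary(T_null)
    rate_null = _offframe_rate(pi_null, T_null, ALL_CODONS, target)
    return float(np.log(rate_true / rate_null))
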