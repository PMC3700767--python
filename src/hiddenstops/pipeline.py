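"""End-to-end orchestration shared by the command-line interface and tests.

A "scan" of one organism: train the order-k 3-periodic model on the filtered
transcriptome, generate N randomized replicates, and compare observed to
replicate off-frame counts for the pooled stop set and each of the 64 codons
individually.  One replicate stream serves all 65 targets at once — an
equivalent but much cheaper schedule than re-randomizing per target.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encode import CODONS, codon_index
from .excess import ExcessResult, PanelSummary, excess, summarize_panel
from .genetic_code import DEFAULT_STOPS
from .markov import PeriodicMarkovModel, ReplicateSet, generate_replicate_counts, train
from .offframe import ALL_STOPS, count64_transcriptome
from .transcripts import Transcriptome, gc_content

#: scan targets: pooled stops first, then every codon individually
SCAN_TARGETS: tuple[str, ...] = (ALL_STOPS,) + CODONS


def _target_indices(target: str) -> list[int]:
    if target == ALL_STOPS:
        return [codon_index(c) for c in sorted(DEFAULT_STOPS)]
    return [codon_index(target)]


@dataclass
class OrganismScan:
    organism_id: str
    order: int
    gc: float
    results: list[ExcessResult]
    fallback_draws: int
    model: PeriodicMarkovModel
    replicates: ReplicateSet

    def result_for(self, target: str) -> ExcessResult:
        for r in self.results:
            if r.target == target:
                return r
        raise KeyError(target)


def scan_organism(
    t: Transcriptome,
    order: int = 2,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
) -> OrganismScan:
    """Full observed-vs-expected scan of one filtered transcriptome at one order."""
    model = train(t, order)
    reps = generate_replicate_counts(model, t, n=n_replicates, rng=seed)
    obs1, obs2 = count64_transcriptome(t)
    obs_total = obs1 + obs2
    results = []
    for target in SCAN_TARGETS:
        idx = _target_indices(target)
        observed = int(obs_total[idx].sum())
        rep_totals = reps.totals_for(idx)
        results.append(
            excess(observed, rep_totals, alpha=alpha, organism_id=t.organism_id, target=target)
        )
    return OrganismScan(
        organism_id=t.organism_id,
        order=order,
        gc=gc_content(t),
        results=results,
        fallback_draws=reps.fallback_draws,
        model=model,
        replicates=reps,
    )


def scan_panel(
    transcriptomes: list[Transcriptome],
    orders=(2,),
    n_replicates: int = 200,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> list[OrganismScan]:
    """Scan every organism at every order.

    Organisms are independent work units; organism i at order position j uses
    the deterministic seed (base_seed + 10007*i + j) mod 2^31, so any execution
    order (or parallel split) reproduces identical per-organism output.
    """
    scans = []
    for i, t in enumerate(transcriptomes):
        for j, order in enumerate(orders):
            seed = (base_seed + 10_007 * i + j) % (2**31)
            scans.append(
                scan_organism(t, order=order, n_replicates=n_replicates, alpha=alpha, seed=seed)
            )
    return scans


def panel_summaries(scans: list[OrganismScan]) -> list[tuple[int, PanelSummary]]:
    """Per-order, per-target cross-organism summaries (targets lacking three
    organisms with defined L are skipped)."""
    out = []
    orders = sorted({s.order for s in scans})
    for order in orders:
        sub = [s for s in scans if s.order == order]
        gc_map = {s.organism_id: s.gc for s in sub}
        flat = [r for s in sub for r in s.results]
        for target in SCAN_TARGETS:
            try:
                out.append((order, summarize_panel(flat, gc_map, target)))
            except ValueError:
                continue
    return out
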