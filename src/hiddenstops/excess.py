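"""Observed-vs-expected off-frame excess: log-ratio statistic and panel summaries.

For a target codon (or the pooled stop set) with observed off-frame count O and
replicate counts E_1..E_N from the trained null model, the excess statistic is

    L = ln(O / mean(E)),

positive when the codon occurs off-frame more often than the null predicts.
The log removes the upward bias a plain ratio has under symmetric noise, and is
antisymmetric under swapping observed with expected.  Significance is an
empirical one-sided rank test against the replicates with add-one correction,
so p is never smaller than 1/(N+1); a normal-approximation z-test p-value is
reported alongside for comparison but does not govern the significance flag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ExcessResult:
    organism_id: str
    target: str
    observed: int
    expected_mean: float
    expected_sd: float
    log_ratio: float  # nan when undefined (O>0, E=0); -inf when O=0, E>0
    p_emp: float
    p_norm: float
    significant_excess: bool
    n_replicates: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.log_ratio)


def excess(
    observed: int,
    replicate_counts,
    alpha: float = 0.05,
    organism_id: str = "",
    target: str = "",
) -> ExcessResult:
    """Log-ratio excess of ``observed`` against Monte-Carlo replicate counts."""
    reps = np.asarray(replicate_counts, dtype=float)
    if reps.size == 0:
        raise ValueError("need at least one replicate count")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    n = reps.size
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1)) if n > 1 else 0.0
    if mean == 0.0:
        log_ratio = math.nan if observed > 0 else 0.0
    elif observed == 0:
        log_ratio = -math.inf
    else:
        log_ratio = math.log(observed / mean)
    if log_ratio > 0:
        p_emp = (1 + int((reps >= observed).sum())) / (n + 1)
    else:
        p_emp = (1 + int((reps <= observed).sum())) / (n + 1)
    if sd > 0:
        z = (observed - mean) / sd
        p_norm = float(stats.norm.sf(abs(z)))
    else:
        p_norm = 1.0 if observed == mean else 0.0
    return ExcessResult(
        organism_id=organism_id,
        target=target,
        observed=int(observed),
        expected_mean=mean,
        expected_sd=sd,
        log_ratio=log_ratio,
        p_emp=p_emp,
        p_norm=p_norm,
        significant_excess=bool(log_ratio > 0 and p_emp < alpha),
        n_replicates=n,
    )


def per_gene_excess(observed: int, expected_mean: float, n_genes: int) -> float:
    """Absolute excess spread over the gene count: (O - E) / n_genes."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return (observed - expected_mean) / n_genes


def percent_excess(results: list[ExcessResult]) -> float:
    """Percentage of organisms with raw L > 0 (sign-based, not significance-based)."""
    if not results:
        raise ValueError("no results")
    return 100.0 * sum(1 for r in results if r.log_ratio > 0) / len(results)


def gc_excess_regression(points) -> tuple[float, float, float]:
    """OLS of log-ratio on GC content: (slope, intercept, pearson_r).

    ``points`` is an iterable of (gc, L) pairs; GC is a fraction in [0, 1].
    """
    pts = [(g, l) for g, l in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 organisms for a GC regression")
    gc = np.array([p[0] for p in pts])
    lr = np.array([p[1] for p in pts])
    if np.ptp(gc) == 0:
        raise ValueError("GC content has zero variance")
    if np.ptp(lr) == 0:
        return 0.0, float(lr[0]), 0.0
    fit = stats.linregress(gc, lr)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


@dataclass
class PanelSummary:
    target: str
    n_organisms: int
    pct_excess: float
    mean_log_ratio: float
    gc_slope: float
    gc_intercept: float
    gc_pearson_r: float
    n_undefined: int = 0


def summarize_panel(results: list[ExcessResult], gc_by_organism: dict[str, float], target: str) -> PanelSummary:
    """Cross-organism aggregation for one target: % with excess, mean L, GC fit.

    Organisms with undefined or infinite L for this target are dropped from the
    row (their count is reported) — they carry no usable ratio.
    """
    rows = [r for r in results if r.target == target]
    defined = [r for r in rows if r.defined]
    n_undefined = len(rows) - len(defined)
    if len(defined) < 3:
        raise ValueError(f"need >= 3 organisms with defined L for target {target}")
    slope, intercept, r = gc_excess_regression(
        (gc_by_organism[x.organism_id], x.log_ratio) for x in defined
    )
    return PanelSummary(
        target=target,
        n_organisms=len(defined),
        pct_excess=percent_excess(defined),
        mean_log_ratio=float(np.mean([x.log_ratio for x in defined])),
        gc_slope=slope,
        gc_intercept=intercept,
        gc_pearson_r=r,
        n_undefined=n_undefined,
    )
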