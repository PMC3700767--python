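"""Codon usage versus OSC potential, and its dependence on GC content.

Each organism contributes one Spearman rank correlation (and one OLS slope)
between the relative usage of its 61 sense codons and each codon's 0–6
potential to form an off-frame stop with a neighbor.  Because stop codons are
AT-rich, high-potential codons are AT-rich too, so this correlation tracks
genomic GC content: AT-rich organisms show positive correlations, GC-rich ones
negative, and across a panel the per-organism OLS slope falls almost linearly
with GC.  That panel regression is the quantity of interest here — it measures
how completely GC content explains the usage/potential relationship.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetic_code import GeneticCode, potential_table


@dataclass
class UsagePotentialResult:
    organism_id: str
    gc: float
    spearman_rho: float  # nan when usage has zero variance
    spearman_p: float
    ols_slope: float
    ols_intercept: float
    significant_positive: bool
    significant_negative: bool
    n_codons: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.spearman_rho)


def usage_vs_potential(
    usage: dict[str, float],
    code: GeneticCode | None = None,
    organism_id: str = "",
    gc: float = float("nan"),
    alpha: float = 0.05,
    grouped: bool = False,
) -> UsagePotentialResult:
    """Spearman correlation and OLS fit of sense-codon usage against OSC potential.

    The 61 sense codons are the data points (potential values repeat; ties get
    average ranks).  ``grouped=True`` instead correlates the 7 mean usages of
    the potential classes 0..6 — a coarser variant provided for comparison.
    Stop codons never enter.
    """
    if code is None:
        code = GeneticCode.standard()
    sense = code.sense_codons
    missing = [c for c in sense if c not in usage]
    if missing:
        raise ValueError(f"usage map missing sense codons, e.g. {missing[0]}")
    pot_full = potential_table(code)
    u = np.array([usage[c] for c in sense], dtype=float)
    w = np.array([pot_full[c] for c in sense], dtype=float)
    if grouped:
        levels = np.unique(w)
        u = np.array([u[w == lv].mean() for lv in levels])
        w = levels
    n = u.size
    slope, intercept = _ols(w, u)
    if np.ptp(u) == 0:
        rho, p = float("nan"), 1.0
    else:
        rho, p = stats.spearmanr(w, u)
        rho, p = float(rho), float(p)
    return UsagePotentialResult(
        organism_id=organism_id,
        gc=gc,
        spearman_rho=rho,
        spearman_p=p,
        ols_slope=slope,
        ols_intercept=intercept,
        significant_positive=bool(np.isfinite(rho) and rho > 0 and p < alpha),
        significant_negative=bool(np.isfinite(rho) and rho < 0 and p < alpha),
        n_codons=n,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(y) == 0:
        return 0.0, float(y[0])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def slope_vs_gc(
    results: list[UsagePotentialResult], gc_units: str = "fraction"
) -> tuple[float, float, float]:
    """Panel OLS of per-organism usage-vs-potential slope on GC content.

    Returns (slope, intercept, r_squared).  ``gc_units`` is "fraction" (GC in
    [0,1], the default) or "percent" (GC × 100).
    """
    if gc_units not in ("fraction", "percent"):
        raise ValueError("gc_units must be 'fraction' or 'percent'")
    if len(results) < 3:
        raise ValueError("need at least 3 organisms")
    scale = 100.0 if gc_units == "percent" else 1.0
    gc = np.array([r.gc for r in results]) * scale
    sl = np.array([r.ols_slope for r in results])
    if np.ptp(gc) == 0:
        raise ValueError("GC content has zero variance")
    fit = stats.linregress(gc, sl)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def classify_panel(results: list[UsagePotentialResult]) -> dict[str, int]:
    """Tally organisms by Spearman significance and sign at the stored alpha."""
    if not results:
        raise ValueError("no results")
    sig_pos = sum(1 for r in results if r.significant_positive)
    sig_neg = sum(1 for r in results if r.significant_negative)
    return {
        "sig_pos": sig_pos,
        "sig_neg": sig_neg,
        "nonsig": len(results) - sig_pos - sig_neg,
    }
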