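"""Budget-table accounting and uncertainty bookkeeping.

The global carbon budget identity is

    fossil = growth + ocean + land + imbalance      [Pg C/yr]

Routines here compute the imbalance, apply multiplicative scenario
adjustments (e.g. fossil x0.94, ocean x1.08), propagate independent
1-sigma Gaussian uncertainties in quadrature, derive a residual-term
uncertainty from the other terms, recalibrate an ocean-sink series to a
data-constrained window mean, and cross-check quadrature propagation
against Monte Carlo.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .containers import BUDGET_TERMS, BudgetTable, Uncertain


def budget_imbalance(budget: BudgetTable | dict) -> float:
    """fossil - growth - ocean - land, Pg C/yr, from period means."""
    means = budget.means if isinstance(budget, BudgetTable) else budget
    missing = [t for t in BUDGET_TERMS if t not in means]
    if missing:
        raise ValueError(f"missing budget terms: {missing}")

    def val(term):
        u = means[term]
        return u.value if isinstance(u, Uncertain) else float(u)

    return val("fossil") - val("growth") - val("ocean") - val("land")


def close_budget(
    budget: BudgetTable, adjustments: dict[str, float]
) -> tuple[BudgetTable, dict]:
    """Apply multiplicative scenario adjustments to a budget table.

    ``adjustments`` maps term -> multiplier (e.g. {"fossil": 0.94,
    "ocean": 1.08}). Uncertainties scale with their terms. The report
    lists each absolute adjustment in Pg C/yr and the residual imbalance
    of the adjusted table. Adjusting the atmospheric growth rate by more
    than 1% draws a hard warning: that term is measured too precisely to
    be a plausible tuning knob.
    """
    for term, mult in adjustments.items():
        if mult <= 0:
            raise ValueError("multipliers must be positive")
        if term not in BUDGET_TERMS:
            raise ValueError(f"unknown budget term {term!r}")
        if term == "growth" and abs(mult - 1.0) > 0.01:
            warnings.warn(
                "adjusting the atmospheric growth rate by more than 1% — "
                "this term is well known",
                stacklevel=2,
            )
    means = {}
    report = {"adjustments_pgc_yr": {}}
    for term, u in budget.means.items():
        mult = adjustments.get(term, 1.0)
        means[term] = Uncertain(u.value * mult, u.sigma * mult)
        if term in adjustments:
            report["adjustments_pgc_yr"][term] = u.value * (mult - 1.0)
    series = budget.series.copy() if budget.series is not None else None
    series_sigma = (
        budget.series_sigma.copy() if budget.series_sigma is not None else None
    )
    for term, mult in adjustments.items():
        if series is not None and term in series:
            series[term] *= mult
        if series_sigma is not None and term in series_sigma:
            series_sigma[term] *= mult
    adjusted = BudgetTable(
        means=means, period=budget.period, series=series, series_sigma=series_sigma
    )
    report["residual_imbalance_pgc_yr"] = budget_imbalance(adjusted)
    return adjusted, report


def quadrature(sigmas) -> float:
    """Square root of the sum of squared independent 1-sigma values."""
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("need at least one sigma")
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be non-negative")
    return math.sqrt(sum(s * s for s in sigmas))


def residual_uncertainty(known_sigmas, reference_mean: float) -> tuple[float, float]:
    """Uncertainty of a residual budget term from the other terms' sigmas.

    Returns (absolute 1-sigma in Pg C/yr, percent of ``reference_mean``).
    This is the reverse of the classic land-sink-by-difference
    calculation: when land is measured and fossil becomes the residual,
    the fossil uncertainty inherits the quadrature sum of the others.
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    sig = quadrature(known_sigmas)
    return sig, 100.0 * sig / reference_mean


def percent_difference(a: float, b: float) -> float:
    """100*(a - b)/b — signed percent difference of a relative to b."""
    if b == 0:
        raise ValueError("zero reference value")
    return 100.0 * (a - b) / b


def calibrate_ocean_scale(
    ocean_series: pd.Series,
    window: tuple[int, int],
    target_mean: float,
    natural_loss_adjustment: float = 0.0,
) -> tuple[float, pd.Series]:
    """Rescale an ocean-sink series to match a data-constrained window mean.

    The multiplicative scale is (target_mean + natural_loss_adjustment)
    divided by the series mean over ``window``; the whole series is
    scaled so interannual structure is preserved. The adjustment term
    accounts for a natural (climate-driven) ocean carbon loss component
    absent from the anthropogenic data constraint.
    """
    sub = ocean_series.loc[window[0] : window[1]]
    if sub.empty:
        raise ValueError("calibration window outside the series")
    wmean = float(sub.mean())
    if wmean == 0:
        raise ValueError("zero window mean")
    scale = (target_mean + natural_loss_adjustment) / wmean
    return scale, ocean_series * scale


def mc_propagation_check(
    budget: BudgetTable, n: int = 100_000, seed: int = 0
) -> dict:
    """Monte-Carlo check of quadrature propagation for the budget residual.

    Draws independent Gaussian realisations of all four terms, forms the
    residual fossil - growth - ocean - land, and compares its sampled
    standard deviation with the quadrature sum of the input sigmas.
    """
    if n < 10_000:
        raise ValueError("n must be at least 1e4 for a stable check")
    rng = np.random.default_rng(seed)
    sigmas = [budget.means[t].sigma for t in BUDGET_TERMS]
    quad = quadrature(sigmas) if any(s > 0 for s in sigmas) else 0.0
    draws = sum(
        sgn * rng.normal(budget.means[t].value, budget.means[t].sigma, n)
        for t, sgn in zip(BUDGET_TERMS, (1.0, -1.0, -1.0, -1.0))
    )
    mc_sigma = float(np.std(draws, ddof=1)) if quad > 0 else 0.0
    rel = abs(mc_sigma - quad) / quad if quad > 0 else 0.0
    return {
        "quadrature_sigma": quad,
        "mc_sigma": mc_sigma,
        "relative_discrepancy": rel,
        "n": n,
        "seed": seed,
    }


def budget_report(budget: BudgetTable, reference: BudgetTable | None = None) -> str:
    """Human-readable budget table, optionally with percent differences."""
    lines = [f"{'Term':<12}{'Mean':>8}{'1sigma':>8}" + ("{:>10}".format("% diff") if reference else "")]
    for term in BUDGET_TERMS:
        u = budget.means[term]
        row = f"{term:<12}{u.value:>8.1f}{u.sigma:>8.1f}"
        if reference is not None:
            row += f"{percent_difference(u.value, reference.means[term].value):>10.0f}"
        lines.append(row)
    lines.append(f"imbalance   {budget_imbalance(budget):>8.2f}")
    return "\n".join(lines)
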