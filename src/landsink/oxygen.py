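"""Joint atmospheric O2/CO2 budget: forward simulation and sink partitioning.

Fossil fuel combustion consumes O2 in proportion to its oxidative ratio
alpha_f, carbon storage on land releases O2 in proportion to alpha_b,
and the ocean carbon sink is O2-neutral because it is mediated by
carbonate chemistry and mixing rather than organic matter. A net ocean
O2 outgassing term z (from warming-driven ventilation changes) can be
prescribed. In Pg C-equivalent units,

    dO2/dt = -alpha_f * F_fossil + alpha_b * B + z

Together with the carbon budget F_fossil = dCO2/dt + B + O this is a
linear 2x2 system: the observed O2 trend fixes the land sink B, and the
ocean sink O follows as the carbon-budget residual. A reduced fossil
flux lowers B by alpha_f/alpha_b times the reduction and raises O by
(alpha_f/alpha_b - 1) times it, which is why the same fossil adjustment
that weakens the inferred land sink strengthens the inferred ocean sink.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants
from .containers import OxygenSeries, SinkPartition, Stoichiometry, Uncertain


def per_meg_conversion(
    rate_per_meg: float, stoich: Stoichiometry = Stoichiometry()
) -> tuple[float, float]:
    """Convert an O2/N2 trend (per meg/yr) to mol O2/yr and Pg C-equivalent/yr."""
    if stoich.o2_mole_fraction <= 0 or stoich.air_moles <= 0:
        raise ValueError("molar constants must be positive")
    mol = rate_per_meg * 1e-6 * stoich.o2_mole_fraction * stoich.air_moles
    pgc_equiv = mol * constants.GRAMS_C_PER_MOL * 1e-15
    return mol, pgc_equiv


def pgc_to_per_meg(rate_pgc_equiv: float, stoich: Stoichiometry = Stoichiometry()) -> float:
    """Inverse unit bridge: Pg C-equivalent/yr to per meg/yr."""
    mol = rate_pgc_equiv / (constants.GRAMS_C_PER_MOL * 1e-15)
    return mol / (1e-6 * stoich.o2_mole_fraction * stoich.air_moles)


def forward_o2_budget(
    fossil: float, land_sink: float, stoich: Stoichiometry = Stoichiometry()
) -> tuple[float, float]:
    """Atmospheric O2 tendency for given fossil emissions and land sink.

    Returns (Pg C-equivalent/yr, per meg/yr); negative = O2 decline.
    """
    d_o2 = -stoich.alpha_f * fossil + stoich.alpha_b * land_sink + stoich.z_ocean
    return d_o2, pgc_to_per_meg(d_o2, stoich)


def fit_trend(series: OxygenSeries | pd.Series, window: tuple[float, float] | None = None) -> float:
    """Ordinary-least-squares linear trend of an annual series (units/yr)."""
    s = series.data if isinstance(series, OxygenSeries) else series
    if window is not None:
        s = s.loc[window[0] : window[1]]
    if len(s) < 2:
        raise ValueError("need at least 2 points to fit a trend")
    years = s.index.to_numpy(dtype=float)
    slope = np.polyfit(years, s.to_numpy(dtype=float), 1)[0]
    return float(slope)


def mean_rate(series: OxygenSeries | pd.Series) -> float:
    """Mean annual rate as the endpoint difference over the span (units/yr).

    For a record built by accumulating annual tendencies this recovers
    the exact mean tendency, whereas an OLS slope of the levels does not
    when the tendency varies over time.
    """
    s = series.data if isinstance(series, OxygenSeries) else series
    if len(s) < 2:
        raise ValueError("need at least 2 points")
    span = float(s.index[-1] - s.index[0])
    return float((s.iloc[-1] - s.iloc[0]) / span)


def partition_sinks(
    d_co2: float,
    d_o2: float,
    fossil: Uncertain | float,
    stoich: Stoichiometry = Stoichiometry(),
    mc: dict | None = None,
    d_co2_sigma: float = 0.0,
    d_o2_sigma: float = 0.0,
    scenario: str = "baseline",
) -> SinkPartition:
    """Solve the 2x2 O2/CO2 system for land and ocean sinks.

    Parameters
    ----------
    d_co2
        Atmospheric CO2 growth rate, Pg C/yr.
    d_o2
        Atmospheric O2 trend, Pg C-equivalent/yr (typically negative).
    fossil
        Fossil fuel emissions, Pg C/yr, optionally with 1-sigma.
    mc
        ``{"n": ..., "seed": ...}`` — Monte-Carlo propagation over fossil,
        z_ocean and the two trend uncertainties.
    """
    if stoich.alpha_b == 0:
        raise ValueError("alpha_b = 0 makes the O2 budget singular")
    f = fossil if isinstance(fossil, Uncertain) else Uncertain(float(fossil))

    def solve(d_o2_v, f_v, z_v, d_co2_v):
        b = (d_o2_v + stoich.alpha_f * f_v - z_v) / stoich.alpha_b
        o = f_v - d_co2_v - b
        return b, o

    b, o = solve(d_o2, f.value, stoich.z_ocean, d_co2)
    b_sig = o_sig = 0.0
    meta = {
        "alpha_f": stoich.alpha_f,
        "alpha_b": stoich.alpha_b,
        "z_ocean": stoich.z_ocean,
        "d_co2": d_co2,
        "d_o2_pgc_equiv": d_o2,
    }
    if mc is not None:
        n = int(mc.get("n", 2000))
        rng = np.random.default_rng(mc.get("seed", 0))
        f_k = f.value + rng.normal(0.0, f.sigma, n)
        z_k = stoich.z_ocean + rng.normal(0.0, stoich.z_ocean_sigma, n)
        o2_k = d_o2 + rng.normal(0.0, d_o2_sigma, n)
        co2_k = d_co2 + rng.normal(0.0, d_co2_sigma, n)
        b_k, o_k = solve(o2_k, f_k, z_k, co2_k)
        b_sig = float(np.std(b_k, ddof=1))
        o_sig = float(np.std(o_k, ddof=1))
        meta.update({"mc_n": n, "mc_seed": mc.get("seed", 0)})
    return SinkPartition(
        land=Uncertain(float(b), b_sig),
        ocean=Uncertain(float(o), o_sig),
        scenario=scenario,
        meta=meta,
    )


def fossil_sensitivity(stoich: Stoichiometry = Stoichiometry()) -> tuple[float, float]:
    """Closed-form (dB/dFossil, dOcean/dFossil) at fixed observed trends.

    dB/dF = alpha_f/alpha_b > 1 and dO/dF = 1 - alpha_f/alpha_b < 0 when
    alpha_f > alpha_b: shrinking the fossil inventory moves carbon from
    the inferred land sink into the inferred ocean sink.
    """
    ratio = stoich.alpha_f / stoich.alpha_b
    return ratio, 1.0 - ratio
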