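"""Stock-change pathway: from vegetation-carbon maps to a net land sink.

The stock-change method estimates the net land flux as the change in
measured carbon stocks between two epochs divided by the interval. Only
living vegetation is observable from space, so the vegetation change
dC_VEG is scaled to whole-ecosystem accumulation with an ensemble-derived
scale factor

    S = (dC_VEG + dC_LITTER + dC_SOIL) / dC_VEG = sum(NBP) / dC_VEG

computed per model as cumulative net biome production over the window
divided by the model's vegetation-carbon change, then averaged across
the ensemble. dC_LAND = S * dC_VEG converts the satellite estimate to
total land carbon accumulation, and division by the interval length
(midpoint-to-midpoint) yields the annual flux.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .constants import MG_PER_PG
from .containers import (
    ModelMember,
    ScaleFactor,
    StockChangeEstimate,
    Uncertain,
    check_shared_axes,
)

DEGENERATE_DCVEG_PGC = 0.1


def fuse_products(
    a: Uncertain | None, b: Uncertain | None
) -> Uncertain:
    """Inverse-variance weighted fusion of two independent estimates.

    With equal sigmas the fused sigma shrinks by sqrt(2); a missing
    product passes the other through unchanged. Two zero-variance inputs
    must agree exactly.
    """
    if a is None and b is None:
        raise ValueError("both products missing")
    if a is None:
        return b
    if b is None:
        return a
    if a.sigma == 0 and b.sigma == 0:
        if a.value != b.value:
            raise ValueError("conflicting exact values cannot be fused")
        return Uncertain(a.value, 0.0)
    if a.sigma == 0:
        return a
    if b.sigma == 0:
        return b
    wa, wb = 1.0 / a.sigma**2, 1.0 / b.sigma**2
    var = 1.0 / (wa + wb)
    return Uncertain((wa * a.value + wb * b.value) * var, math.sqrt(var))


def fuse_grids(a: xr.Dataset, b: xr.Dataset) -> xr.Dataset:
    """Cell-wise inverse-variance fusion of two vegetation-carbon grids.

    Cells flagged missing (NaN) in one product take the other's value.
    """
    check_shared_axes(a, b)
    va, vb = a["cveg"].values, b["cveg"].values
    sa, sb = a["cveg_sigma"].values, b["cveg_sigma"].values
    with np.errstate(divide="ignore", invalid="ignore"):
        wa = np.where(np.isnan(va), 0.0, 1.0 / sa**2)
        wb = np.where(np.isnan(vb), 0.0, 1.0 / sb**2)
        fused = (wa * np.nan_to_num(va) + wb * np.nan_to_num(vb)) / (wa + wb)
        sig = np.sqrt(1.0 / (wa + wb))
    out = a.copy(deep=True)
    out["cveg"] = (("lat", "lon"), fused)
    out["cveg_sigma"] = (("lat", "lon"), sig)
    return out


def compute_scale_factor(
    ensemble: list[ModelMember],
    window: tuple[float, float] = (2000.5, 2019.5),
    region: str = "global",
) -> ScaleFactor:
    """Per-model S = cumulative NBP / dC_VEG over the window, averaged.

    NBP is summed over the annual steps inside the window; dC_VEG is the
    difference of the vegetation-carbon stock between the window
    endpoints. Members with |dC_VEG| below 0.1 Pg C are excluded with a
    warning rather than producing unbounded ratios.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    lo, hi = window
    values = {}
    excluded = []
    for member in ensemble:
        years = member.data.index
        start = years[years >= lo].min()
        end = years[years <= hi].max()
        if pd.isna(start) or pd.isna(end) or end <= start:
            raise ValueError(f"member {member.name} does not cover the window")
        dcveg = float(member.data.at[end, "cveg"] - member.data.at[start, "cveg"])
        if abs(dcveg) < DEGENERATE_DCVEG_PGC:
            warnings.warn(
                f"member {member.name} has near-zero vegetation change "
                f"({dcveg:.3g} Pg C); excluded from S",
                stacklevel=2,
            )
            excluded.append(member.name)
            continue
        cum_nbp = float(member.data.loc[start + 1 : end, "nbp"].sum())
        values[member.name] = cum_nbp / dcveg
    if not values:
        raise ValueError("no usable members for the scale factor")
    return ScaleFactor(
        per_model=pd.Series(values, dtype=float),
        region=region,
        window=window,
        excluded=excluded,
    )


def scale_to_land(
    delta_cveg: Uncertain,
    s: ScaleFactor | Uncertain,
    region: str = "global",
    interval: tuple[float, float] = (2000.5, 2019.5),
) -> StockChangeEstimate:
    """dC_LAND = S * dC_VEG with the exact independent-product variance.

    var = S^2 sig_V^2 + V^2 sig_S^2 + sig_S^2 sig_V^2 (cross term
    included).
    """
    su = s.as_uncertain() if isinstance(s, ScaleFactor) else s
    value = su.value * delta_cveg.value
    var = (
        su.value**2 * delta_cveg.sigma**2
        + delta_cveg.value**2 * su.sigma**2
        + su.sigma**2 * delta_cveg.sigma**2
    )
    return StockChangeEstimate(
        delta_cveg=delta_cveg,
        delta_cland=Uncertain(value, math.sqrt(var)),
        region=region,
        interval=interval,
    )


def stock_to_flux(delta: Uncertain, interval_years: float) -> Uncertain:
    """Convert a stock change (Pg C) to a mean annual flux (Pg C/yr).

    The interval follows the midpoint-to-midpoint convention: midpoint
    of 2000 to midpoint of 2019 is 19.0 years.
    """
    if interval_years <= 0:
        raise ValueError("interval must be positive")
    return Uncertain(delta.value / interval_years, delta.sigma / interval_years)


def relative_stock_increase(cumulative: float, end_stock: float) -> float:
    """Percent growth of a stock implied by a cumulative accumulation.

    The start-of-period stock is inferred by subtracting the cumulative
    accumulation from the end-of-period stock, so the result is
    100 * cumulative / (end_stock - cumulative).
    """
    if end_stock <= cumulative:
        raise ValueError("end stock must exceed the cumulative accumulation")
    return 100.0 * cumulative / (end_stock - cumulative)


def relative_change_map(
    early: xr.Dataset, late: xr.Dataset, mask_threshold: float = 1.0
) -> xr.Dataset:
    """Per-cell absolute and percent vegetation-carbon change with a mask.

    Cells whose early-epoch stock is below ``mask_threshold`` (Mg C/ha)
    are flagged masked — percent changes over near-zero baselines are
    not interpretable.
    """
    check_shared_axes(early, late)
    e = early["cveg"].values
    l = late["cveg"].values
    abs_change = l - e
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(e > 0, 100.0 * abs_change / np.where(e > 0, e, 1.0), np.nan)
    mask = e < mask_threshold
    return xr.Dataset(
        {
            "abs_change": (("lat", "lon"), abs_change),
            "percent_change": (("lat", "lon"), pct),
            "mask": (("lat", "lon"), mask),
            "cell_area": (("lat", "lon"), early["cell_area"].values),
        },
        coords={"lat": early["lat"].values, "lon": early["lon"].values},
        attrs={
            "mask_threshold_mg_c_ha": mask_threshold,
            "early_epoch": early.attrs.get("epoch"),
            "late_epoch": late.attrs.get("epoch"),
        },
    )


def grid_total_change(early: xr.Dataset, late: xr.Dataset, region: str = "global") -> float:
    """Area-weighted total vegetation-carbon change of a grid pair, Pg C.

    Mg C/ha densities times cell areas in ha, summed and converted to
    Pg C. ``region="nh"`` restricts to cells north of the equator.
    """
    check_shared_axes(early, late)
    change = (late["cveg"].values - early["cveg"].values) * early["cell_area"].values
    if region == "nh":
        change = change[early["lat"].values > 0, :]
    elif region != "global":
        raise ValueError("region must be 'global' or 'nh'")
    return float(change.sum() / MG_PER_PG)
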