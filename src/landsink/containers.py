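"""Shared in-memory containers for the carbon budget pipeline.

Year-indexed series live in pandas objects; gridded fields live in
xarray Datasets; small bundles of values with metadata are dataclasses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from . import constants

BUDGET_TERMS = ("fossil", "growth", "ocean", "land")


@dataclass(frozen=True)
class Uncertain:
    """A scalar with a 1-sigma Gaussian uncertainty."""

    value: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def __iter__(self):
        return iter((self.value, self.sigma))


@dataclass
class BudgetTable:
    """Global carbon budget ledger: fossil = growth + ocean + land (+ imbalance).

    Parameters
    ----------
    means
        Period-mean flux per term, Pg C/yr with 1-sigma.
    period
        Inclusive (start, end) calendar years.
    series
        Optional year-indexed annual values (columns = terms), Pg C/yr.
    series_sigma
        Optional per-year 1-sigma values matching ``series``.
    """

    means: dict[str, Uncertain]
    period: tuple[int, int]
    series: pd.DataFrame | None = None
    series_sigma: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.period[1] < self.period[0]:
            raise ValueError("period end must be >= period start")
        for term in self.means:
            if term not in BUDGET_TERMS and term != "imbalance":
                raise ValueError(f"unknown budget term {term!r}")

    @classmethod
    def from_series(
        cls,
        series: pd.DataFrame,
        series_sigma: pd.DataFrame | None = None,
    ) -> "BudgetTable":
        """Build a table from year-indexed annual values.

        Period means are arithmetic means over the whole year range; the
        1-sigma of a mean is taken as the mean per-year sigma (budget-term
        errors are treated as systematic across years, not independent).
        """
        if series.empty:
            raise ValueError("budget series is empty")
        years = series.index
        means = {}
        for term in series.columns:
            sig = 0.0
            if series_sigma is not None and term in series_sigma:
                sig = float(series_sigma[term].mean())
            means[term] = Uncertain(float(series[term].mean()), sig)
        return cls(
            means=means,
            period=(int(years.min()), int(years.max())),
            series=series,
            series_sigma=series_sigma,
        )

    def term_series(self, term: str) -> pd.Series:
        if self.series is None:
            raise ValueError("budget table carries period means only")
        return self.series[term]


@dataclass
class StationSeries:
    """Annual-mean CO2 record at one station (hemispheric proxy)."""

    data: pd.Series  # year index, ppm
    hemisphere: str  # "N" or "S"
    sigma: float = 0.0  # ppm, per annual mean

    def __post_init__(self) -> None:
        years = self.data.index.to_numpy()
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValueError("station years must be strictly increasing")
        if np.any(self.data.to_numpy() <= 0):
            raise ValueError("concentrations must be positive")
        if self.hemisphere not in ("N", "S"):
            raise ValueError("hemisphere must be 'N' or 'S'")


@dataclass
class OxygenSeries:
    """Annual-mean atmospheric O2/N2 record, in per meg."""

    data: pd.Series  # year index, per meg
    station: str = "global"
    sigma: float = 0.0  # per meg

    def __post_init__(self) -> None:
        years = self.data.index.to_numpy()
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class TransportParams:
    """Two-box transport parameters.

    tau : interhemispheric exchange time, years.
    kappa_global : Pg C per ppm for the whole atmosphere; each hemispheric
        box carries half of it.
    """

    tau: float = constants.TAU_DEFAULT
    kappa_global: float = constants.KAPPA_GLOBAL_DEFAULT

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kappa_global <= 0:
            raise ValueError("kappa_global must be positive")

    @property
    def kappa_hemisphere(self) -> float:
        return self.kappa_global / 2.0


@dataclass
class HemisphericFluxSeries:
    """Fossil and ocean fluxes split by hemisphere, Pg C/yr.

    Columns of ``data``: fossil_n, fossil_s, ocean_n, ocean_s.
    ``sigma`` optionally carries matching 1-sigma columns.
    """

    data: pd.DataFrame
    sigma: pd.DataFrame | None = None

    REQUIRED = ("fossil_n", "fossil_s", "ocean_n", "ocean_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing flux columns: {missing}")

    @property
    def years(self) -> pd.Index:
        return self.data.index

    def global_term(self, term: str) -> pd.Series:
        return self.data[f"{term}_n"] + self.data[f"{term}_s"]


@dataclass
class InversionResult:
    """Hemispheric net land sinks recovered by the two-box inversion.

    ``data`` columns: bn, bs (Pg C/yr) and, when Monte Carlo was run,
    bn_sigma, bs_sigma. ``draws`` holds the raw Monte-Carlo ensemble of
    bn trajectories (n_draws x n_years) for downstream aggregation.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)
    draws: np.ndarray | None = None

    @property
    def bn(self) -> pd.Series:
        return self.data["bn"]

    @property
    def bs(self) -> pd.Series:
        return self.data["bs"]


@dataclass(frozen=True)
class Stoichiometry:
    """Constants of the joint O2/CO2 budget.

    alpha_f, alpha_b : molar O2:C ratios for fossil combustion and
        biospheric carbon storage.
    z_ocean : net ocean O2 outgassing expressed in Pg C-equivalent/yr
        (positive adds O2 to the atmosphere), with 1-sigma.
    """

    alpha_f: float = constants.ALPHA_F_DEFAULT
    alpha_b: float = constants.ALPHA_B_DEFAULT
    z_ocean: float = 0.0
    z_ocean_sigma: float = 0.0
    o2_mole_fraction: float = constants.O2_MOLE_FRACTION
    air_moles: float = constants.AIR_MOLES

    def __post_init__(self) -> None:
        if self.alpha_f <= 0 or self.alpha_b <= 0:
            raise ValueError("oxidative ratios must be positive")


@dataclass
class SinkPartition:
    """Land and ocean sinks from the O2/CO2 partitioning, Pg C/yr."""

    land: Uncertain
    ocean: Uncertain
    scenario: str = "baseline"
    meta: dict = field(default_factory=dict)


@dataclass
class StockChangeEstimate:
    """Interval carbon-stock changes, Pg C, over a stated region and window.

    When vegetation, litter and soil components are all present the total
    must satisfy delta_cland = delta_cveg + delta_clitter + delta_csoil.
    """

    delta_cveg: Uncertain | None = None
    delta_clitter: Uncertain | None = None
    delta_csoil: Uncertain | None = None
    delta_cland: Uncertain | None = None
    region: str = "global"
    interval: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        start, end = self.interval
        if end <= start:
            raise ValueError("interval length must be positive")
        parts = (self.delta_cveg, self.delta_clitter, self.delta_csoil)
        if self.delta_cland is not None and all(p is not None for p in parts):
            total = sum(p.value for p in parts)
            if abs(total - self.delta_cland.value) > 1e-9 * max(1.0, abs(total)):
                raise ValueError(
                    "delta_cland must equal delta_cveg + delta_clitter + delta_csoil"
                )

    @property
    def interval_years(self) -> float:
        return self.interval[1] - self.interval[0]


@dataclass
class ScaleFactor:
    """Ensemble-derived ratio of whole-ecosystem to vegetation carbon gain."""

    per_model: pd.Series  # model id -> S
    region: str = "global"
    window: tuple[float, float] = (2000.5, 2019.5)
    excluded: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.per_model.mean())

    @property
    def sd(self) -> float:
        if len(self.per_model) < 2:
            return 0.0
        return float(self.per_model.std(ddof=1))

    def as_uncertain(self) -> Uncertain:
        return Uncertain(self.mean, self.sd)


@dataclass
class ModelMember:
    """One ensemble model's annual carbon diagnostics.

    ``data`` columns: nbp (Pg C/yr), cveg (Pg C), gpp, npp (Pg C/yr).
    Optional per-cell fields hold flattened grids of vegetation-carbon
    change and cumulative net biome production for spatial diagnostics.
    """

    name: str
    data: pd.DataFrame
    cell_delta_cveg: np.ndarray | None = None
    cell_cum_nbp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if {"gpp", "npp"} <= set(self.data.columns):
            gpp = self.data["gpp"].to_numpy()
            npp = self.data["npp"].to_numpy()
            ok = ~(np.isnan(gpp) | np.isnan(npp))
            if np.any(npp[ok] > gpp[ok] + 1e-9) or np.any(npp[ok] < -1e-12):
                raise ValueError("require GPP >= NPP >= 0")


def make_biomass_grid(
    lat: np.ndarray,
    lon: np.ndarray,
    density: np.ndarray,
    sigma: np.ndarray | None = None,
    epoch: int | float = 2000,
) -> xr.Dataset:
    """Assemble a vegetation-carbon grid as an xarray Dataset.

    ``density`` is Mg C/ha on cell-centred (lat, lon) axes of a regular
    grid; cell areas (ha) are computed from the spherical cosine-latitude
    formula and stored alongside.
    """
    density = np.asarray(density, dtype=float)
    if density.shape != (len(lat), len(lon)):
        raise ValueError("density shape must be (len(lat), len(lon))")
    if np.any(density < 0):
        raise ValueError("stock densities must be non-negative")
    if sigma is None:
        sigma = np.zeros_like(density)
    area = cell_areas_ha(lat, lon)
    ds = xr.Dataset(
        {
            "cveg": (("lat", "lon"), density),
            "cveg_sigma": (("lat", "lon"), np.asarray(sigma, dtype=float)),
            "cell_area": (("lat", "lon"), area),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"epoch": float(epoch), "units": "Mg C/ha", "area_units": "ha"},
    )
    return ds


def cell_areas_ha(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Areas of regular lat-lon cells centred on (lat, lon), in hectares."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.pi / 180.0 * (lat[1] - lat[0] if len(lat) > 1 else 180.0)
    dlon = np.pi / 180.0 * (lon[1] - lon[0] if len(lon) > 1 else 360.0)
    phi = np.deg2rad(lat)
    band = (
        constants.EARTH_RADIUS_M**2
        * dlon
        * (np.sin(phi + dlat / 2.0) - np.sin(phi - dlat / 2.0))
    )
    return np.repeat(band[:, None], len(lon), axis=1) / 1.0e4


def check_shared_axes(a: xr.Dataset, b: xr.Dataset) -> None:
    if not (
        np.array_equal(a["lat"].values, b["lat"].values)
        and np.array_equal(a["lon"].values, b["lon"].values)
    ):
        raise ValueError("biomass grids do not share axes")
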