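"""Synthetic data generation with known ground truth.

Every input stream the pipeline consumes — a closed budget ledger,
hemispheric station CO2 records, atmospheric O2/N2 records, an ensemble
of model members, and two-epoch vegetation-carbon grids — can be
generated here with a configurable truth, so each downstream stage
(inversion, scale-factor estimation, O2 partitioning, grid summation)
can be checked as a round trip against the truth record that ships with
the data.

Station records are produced by the forward two-box model and O2 records
by the forward O2 budget, so generator and inverse stage share the same
discretisation by construction. Noise is independent Gaussian on annual
values; one master seed spawns a deterministic child seed per stream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BudgetTable,
    HemisphericFluxSeries,
    ModelMember,
    OxygenSeries,
    StationSeries,
    Stoichiometry,
    TransportParams,
    Uncertain,
    make_biomass_grid,
)
from .oxygen import forward_o2_budget
from .twobox import forward_two_box

#: order in which per-stream child seeds are spawned from the master seed
_STREAMS = ("budget", "station", "o2", "ensemble", "biomass")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Defaults emulate the 2000–2019 global budget: fossil emissions
    growing ~2%/yr from 7 Pg C/yr (period mean ~8.5), an ocean sink at
    29% of fossil emissions (~2.5 Pg C/yr), a land sink of 1.6 Pg C/yr
    concentrated 85% in the Northern Hemisphere, per-term sigmas of
    0.4/0.1/0.4/0.6 Pg C/yr, a 17-member ensemble, carbon-use efficiency
    0.5, and a true vegetation-carbon gain of 10.1 Pg C spread sparsely
    over a coarse global grid.
    """

    years: tuple[int, int] = (2000, 2019)
    ff_start: float = 7.0
    ff_growth: float = 0.02
    ocean_fraction_of_ff: float = 0.29
    land_sink_true: float | pd.Series = 1.6
    land_north_fraction: float = 0.85
    noise_sd: dict = field(
        default_factory=lambda: {
            "fossil": 0.4,
            "growth": 0.1,
            "ocean": 0.4,
            "land": 0.6,
        }
    )
    n_models: int = 17
    s_true: np.ndarray | None = None  # drawn ~N(1.6, 0.6) clipped >= 1 if None
    s_mean: float = 1.6
    s_sd: float = 0.6
    cue0: float = 0.5
    gpp_start: float = 120.0
    gpp_growth: float = 0.005
    ensemble_noise_sd: float = 0.0
    grid_shape: tuple[int, int] = (24, 48)
    delta_cveg_true: float = 10.1
    sparse_fraction: float = 0.9
    obs_noise_sd: float = 0.0  # ppm, station records
    o2_noise_sd: float = 0.0  # per meg
    init_north_ppm: float = 370.0
    init_south_ppm: float = 368.0
    ff_north_fraction: float = 0.94
    ocean_north_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[1] - self.years[0] < 1:
            raise ValueError("year range must span at least 2 years")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise sd must be >= 0")
        if self.n_models < 1:
            raise ValueError("need at least one model")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid shape must be positive")
        if not 0.0 <= self.sparse_fraction <= 1.0:
            raise ValueError("sparse_fraction must be in [0, 1]")

    @property
    def year_index(self) -> pd.Index:
        return pd.Index(range(self.years[0], self.years[1] + 1), name="year")

    def child_seed(self, stream: str) -> np.random.SeedSequence:
        """Deterministic per-stream seed spawned from the master seed."""
        return np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))


@dataclass
class TruthRecord:
    """Ground truth carried alongside every generated dataset."""

    land_north: pd.Series | None = None
    land_south: pd.Series | None = None
    s_true: pd.Series | None = None
    delta_cveg: float | None = None
    b_true: pd.Series | None = None  # land sink in the O2 budget, Pg C/yr
    o_true: pd.Series | None = None  # ocean sink in the O2 budget, Pg C/yr
    seeds: dict = field(default_factory=dict)


def _land_series(config: SyntheticConfig) -> pd.Series:
    if isinstance(config.land_sink_true, pd.Series):
        s = config.land_sink_true
        if not s.index.equals(config.year_index):
            raise ValueError("land_sink_true must cover the configured years")
        return s.astype(float)
    return pd.Series(float(config.land_sink_true), index=config.year_index)


def gen_budget_series(config: SyntheticConfig) -> tuple[BudgetTable, TruthRecord]:
    """Closed synthetic budget ledger with the configured land-sink truth.

    Fossil emissions follow an exponential trend with Gaussian noise,
    the ocean sink is a fixed fraction of the fossil trend plus noise,
    the land sink equals the configured truth, and the atmospheric
    growth rate closes the identity exactly — so the stored table always
    satisfies fossil = growth + ocean + land with zero imbalance.
    """
    years = config.year_index
    rng = np.random.default_rng(config.child_seed("budget"))
    k = np.arange(len(years))
    fossil_clean = config.ff_start * (1.0 + config.ff_growth) ** k
    fossil = fossil_clean + rng.normal(0.0, config.noise_sd["fossil"], len(years))
    ocean = (
        config.ocean_fraction_of_ff * fossil_clean
        + rng.normal(0.0, config.noise_sd["ocean"], len(years))
    )
    land = _land_series(config).to_numpy()
    growth = fossil - ocean - land
    series = pd.DataFrame(
        {"fossil": fossil, "growth": growth, "ocean": ocean, "land": land},
        index=years,
    )
    sigma = pd.DataFrame(
        {t: np.full(len(years), config.noise_sd[t]) for t in series.columns},
        index=years,
    )
    truth = TruthRecord(
        land_north=_land_series(config) * config.land_north_fraction,
        land_south=_land_series(config) * (1.0 - config.land_north_fraction),
        seeds={"budget": config.seed},
    )
    return BudgetTable.from_series(series, sigma), truth


def gen_hemispheric_split(
    budget: BudgetTable,
    ff_north_fraction: float,
    ocean_north_fraction: float,
) -> HemisphericFluxSeries:
    """Split global fossil and ocean terms into hemispheric components.

    The split is exact: northern and southern parts sum to the stored
    global term every year, and sigmas are split with the same
    fractions.
    """
    for frac in (ff_north_fraction, ocean_north_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("hemispheric fractions must be in [0, 1]")
    if budget.series is None:
        raise ValueError("need a year-indexed budget series to split")
    fossil = budget.series["fossil"]
    ocean = budget.series["ocean"]
    data = pd.DataFrame(
        {
            "fossil_n": fossil * ff_north_fraction,
            "fossil_s": fossil * (1.0 - ff_north_fraction),
            "ocean_n": ocean * ocean_north_fraction,
            "ocean_s": ocean * (1.0 - ocean_north_fraction),
        }
    )
    sigma = None
    if budget.series_sigma is not None:
        sigma = pd.DataFrame(
            {
                "fossil_n": budget.series_sigma["fossil"] * ff_north_fraction,
                "fossil_s": budget.series_sigma["fossil"] * (1.0 - ff_north_fraction),
                "ocean_n": budget.series_sigma["ocean"] * ocean_north_fraction,
                "ocean_s": budget.series_sigma["ocean"] * (1.0 - ocean_north_fraction),
            }
        )
    return HemisphericFluxSeries(data=data, sigma=sigma)


def gen_station_records(
    hemi: HemisphericFluxSeries,
    land_north: pd.Series,
    land_south: pd.Series,
    params: TransportParams = TransportParams(),
    obs_noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    init_north: float = 370.0,
    init_south: float = 368.0,
) -> tuple[StationSeries, StationSeries, TruthRecord]:
    """Hemispheric-proxy station records from the forward two-box model.

    Noise-free records are exactly the forward-model trajectories;
    Gaussian observation noise is added to each annual mean.
    """
    if not land_north.index.equals(hemi.years) or not land_south.index.equals(hemi.years):
        raise ValueError("land truth must cover the flux years")
    north, south = forward_two_box(
        hemi, land_north, land_south, init_north, init_south, params
    )
    rng = np.random.default_rng(seed)
    if obs_noise_sd > 0:
        north = StationSeries(
            north.data + rng.normal(0.0, obs_noise_sd, len(north.data)),
            hemisphere="N",
            sigma=obs_noise_sd,
        )
        south = StationSeries(
            south.data + rng.normal(0.0, obs_noise_sd, len(south.data)),
            hemisphere="S",
            sigma=obs_noise_sd,
        )
    truth = TruthRecord(land_north=land_north, land_south=land_south)
    return north, south, truth


def gen_o2_records(
    budget: BudgetTable,
    land_sink: pd.Series,
    stoich: Stoichiometry = Stoichiometry(),
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    start_per_meg: float = 0.0,
) -> tuple[OxygenSeries, TruthRecord]:
    """Atmospheric O2/N2 record implied by the budget and a land-sink truth.

    Per-year O2 tendencies from the forward O2 budget are accumulated
    into a per-meg series at year starts (N flux years give N+1 level
    points, mirroring the station records), then Gaussian observation
    noise is added. The endpoint difference of the noise-free record
    over its span recovers the exact mean tendency.
    """
    if budget.series is None:
        raise ValueError("need a year-indexed budget series")
    if not land_sink.index.equals(budget.series.index):
        raise ValueError("land sink truth must cover the budget years")
    fossil = budget.series["fossil"]
    rates = np.array(
        [
            forward_o2_budget(f, b, stoich)[1]
            for f, b in zip(fossil.to_numpy(), land_sink.to_numpy())
        ]
    )
    levels = start_per_meg + np.concatenate([[0.0], np.cumsum(rates)])
    years = budget.series.index
    level_years = pd.Index(range(years[0], years[-1] + 2), name="year")
    rng = np.random.default_rng(seed)
    noisy = levels + rng.normal(0.0, noise_sd, len(levels)) if noise_sd > 0 else levels
    series = OxygenSeries(
        pd.Series(noisy, index=level_years), station="synthetic", sigma=noise_sd
    )
    o_true = fossil - budget.series["growth"] - land_sink
    truth = TruthRecord(b_true=land_sink, o_true=o_true)
    return series, truth


def gen_cmip_ensemble(
    config: SyntheticConfig,
) -> tuple[list[ModelMember], TruthRecord]:
    """Ensemble members whose cumulative NBP is s_true times their dC_VEG.

    Each member carries a vegetation-carbon trajectory with a randomised
    annual increment pattern, NBP defined through the member's own
    stock changes (so the scale-factor round trip is exact in noise-free
    mode), and GPP/NPP series with the configured carbon-use efficiency.
    Per-cell vegetation-change and cumulative-NBP fields are attached
    for spatial variance diagnostics.
    """
    rng = np.random.default_rng(config.child_seed("ensemble"))
    years = config.year_index
    n_years = len(years)
    if config.s_true is not None:
        s_vals = np.asarray(config.s_true, dtype=float)
        if len(s_vals) != config.n_models:
            raise ValueError("s_true must have one value per model")
    else:
        s_vals = np.maximum(1.0, rng.normal(config.s_mean, config.s_sd, config.n_models))
    members = []
    names = [f"model{i:02d}" for i in range(config.n_models)]
    n_cells = 200
    for name, s in zip(names, s_vals):
        total_dcveg = rng.uniform(5.0, 20.0)
        weights = rng.uniform(0.5, 1.5, n_years - 1)
        increments = total_dcveg * weights / weights.sum()
        cveg = 450.0 + np.concatenate([[0.0], np.cumsum(increments)])
        nbp = s * np.concatenate([[increments[0]], increments])
        if config.ensemble_noise_sd > 0:
            nbp = nbp + rng.normal(0.0, config.ensemble_noise_sd, n_years)
        k = np.arange(n_years)
        gpp = config.gpp_start * (1.0 + config.gpp_growth) ** k
        npp = config.cue0 * gpp
        cell_dcveg = rng.uniform(0.0, 1.0, n_cells) * (
            rng.uniform(size=n_cells) > 0.7
        )
        cell_cum_nbp = s * cell_dcveg
        if config.ensemble_noise_sd > 0:
            cell_cum_nbp = cell_cum_nbp + rng.normal(
                0.0, config.ensemble_noise_sd, n_cells
            )
        members.append(
            ModelMember(
                name=name,
                data=pd.DataFrame(
                    {"nbp": nbp, "cveg": cveg, "gpp": gpp, "npp": npp}, index=years
                ),
                cell_delta_cveg=cell_dcveg,
                cell_cum_nbp=cell_cum_nbp,
            )
        )
    truth = TruthRecord(s_true=pd.Series(s_vals, index=names))
    return members, truth


def gen_biomass_maps(
    config: SyntheticConfig,
) -> tuple["xr.Dataset", "xr.Dataset", TruthRecord]:
    """Two-epoch vegetation-carbon grids with an exact global change.

    The early epoch is a heterogeneous density field (including cells
    below 1 Mg C/ha, which downstream relative-change maps mask); the
    late epoch adds accumulation confined to a random
    (1 - sparse_fraction) subset of cells, scaled so the area-weighted
    global change equals ``delta_cveg_true`` exactly.
    """
    import xarray as xr  # deferred: keeps module import light

    rng = np.random.default_rng(config.child_seed("biomass"))
    nlat, nlon = config.grid_shape
    dlat, dlon = 180.0 / nlat, 360.0 / nlon
    lat = -90.0 + dlat / 2.0 + dlat * np.arange(nlat)
    lon = -180.0 + dlon / 2.0 + dlon * np.arange(nlon)
    density = rng.gamma(shape=1.2, scale=40.0, size=(nlat, nlon))
    # a few near-bare cells sit under the 1 Mg C/ha mask threshold
    bare = rng.uniform(size=density.shape) < 0.15
    density[bare] = rng.uniform(0.0, 0.9, size=int(bare.sum()))
    early = make_biomass_grid(lat, lon, density, sigma=0.2 * density, epoch=config.years[0])
    active = rng.uniform(size=(nlat, nlon)) >= config.sparse_fraction
    if not active.any():
        active[rng.integers(nlat), rng.integers(nlon)] = True
    change = np.where(active, rng.uniform(0.5, 1.5, size=(nlat, nlon)), 0.0)
    area = early["cell_area"].values
    total = (change * area).sum() / 1.0e9  # Pg C before scaling
    change *= config.delta_cveg_true / total
    late = make_biomass_grid(
        lat,
        lon,
        density + change,
        sigma=0.2 * (density + change),
        epoch=config.years[1],
    )
    truth = TruthRecord(delta_cveg=config.delta_cveg_true)
    return early, late, truth


def generate_all(config: SyntheticConfig) -> dict:
    """Generate every input stream from one config and master seed."""
    budget, budget_truth = gen_budget_series(config)
    hemi = gen_hemispheric_split(
        budget, config.ff_north_fraction, config.ocean_north_fraction
    )
    north, south, station_truth = gen_station_records(
        hemi,
        budget_truth.land_north,
        budget_truth.land_south,
        obs_noise_sd=config.obs_noise_sd,
        seed=config.child_seed("station"),
        init_north=config.init_north_ppm,
        init_south=config.init_south_ppm,
    )
    o2, o2_truth = gen_o2_records(
        budget,
        budget.series["land"],
        noise_sd=config.o2_noise_sd,
        seed=config.child_seed("o2"),
    )
    members, ens_truth = gen_cmip_ensemble(config)
    early, late, grid_truth = gen_biomass_maps(config)
    truth = TruthRecord(
        land_north=budget_truth.land_north,
        land_south=budget_truth.land_south,
        s_true=ens_truth.s_true,
        delta_cveg=grid_truth.delta_cveg,
        b_true=o2_truth.b_true,
        o_true=o2_truth.o_true,
        seeds={"master": config.seed},
    )
    return {
        "budget": budget,
        "hemi": hemi,
        "north": north,
        "south": south,
        "o2": o2,
        "members": members,
        "grid_early": early,
        "grid_late": late,
        "truth": truth,
    }
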