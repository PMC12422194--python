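"""Plain-text and netCDF I/O for the pipeline's data streams.

Year-indexed records travel as CSV with a ``year,value,sigma`` header
(one file per term or station); budget period means as
``term,mean,sigma`` CSV; grids as netCDF (scipy backend, netCDF3) with
``cveg``/``cveg_sigma`` in Mg C/ha on (lat, lon); truth and result
records as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .containers import (
    BUDGET_TERMS,
    BudgetTable,
    InversionResult,
    ModelMember,
    OxygenSeries,
    StationSeries,
    Uncertain,
)
from .synth import TruthRecord


def write_year_series(path: Path | str, values: pd.Series, sigma: float | pd.Series = 0.0) -> None:
    sig = sigma if isinstance(sigma, pd.Series) else pd.Series(sigma, index=values.index)
    df = pd.DataFrame({"year": values.index, "value": values.to_numpy(), "sigma": sig.to_numpy()})
    df.to_csv(path, index=False)


def read_year_series(path: Path | str) -> tuple[pd.Series, pd.Series]:
    df = pd.read_csv(path)
    idx = pd.Index(df["year"].astype(int), name="year")
    return (
        pd.Series(df["value"].to_numpy(), index=idx),
        pd.Series(df.get("sigma", 0.0), index=idx) if "sigma" in df else pd.Series(0.0, index=idx),
    )


def write_station(path: Path | str, station: StationSeries) -> None:
    write_year_series(path, station.data, station.sigma)


def read_station(path: Path | str, hemisphere: str) -> StationSeries:
    values, sigma = read_year_series(path)
    return StationSeries(values, hemisphere=hemisphere, sigma=float(sigma.iloc[0]))


def read_oxygen(path: Path | str, station: str = "station") -> OxygenSeries:
    values, sigma = read_year_series(path)
    return OxygenSeries(values, station=station, sigma=float(sigma.iloc[0]))


def write_budget_series(outdir: Path | str, budget: BudgetTable) -> None:
    """One year,value,sigma CSV per budget term."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if budget.series is None:
        raise ValueError("budget table carries no year series")
    for term in budget.series.columns:
        sig = (
            budget.series_sigma[term]
            if budget.series_sigma is not None and term in budget.series_sigma
            else 0.0
        )
        write_year_series(outdir / f"{term}.csv", budget.series[term], sig)


def read_budget_series(indir: Path | str) -> BudgetTable:
    indir = Path(indir)
    series, sigma = {}, {}
    for term in BUDGET_TERMS:
        path = indir / f"{term}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing budget term file {path}")
        series[term], sigma[term] = read_year_series(path)
    return BudgetTable.from_series(pd.DataFrame(series), pd.DataFrame(sigma))


def write_budget_means(path: Path | str, budget: BudgetTable) -> None:
    rows = [
        {"term": term, "mean": u.value, "sigma": u.sigma}
        for term, u in budget.means.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_budget_means(path: Path | str, period: tuple[int, int] = (2000, 2019)) -> BudgetTable:
    df = pd.read_csv(path)
    means = {
        row["term"]: Uncertain(float(row["mean"]), float(row["sigma"]))
        for _, row in df.iterrows()
    }
    return BudgetTable(means=means, period=period)


def write_inversion(path: Path | str, result: InversionResult) -> None:
    df = result.data.rename_axis("year").reset_index()
    df.to_csv(path, index=False)
    meta_path = Path(path).with_suffix(".meta.json")
    meta_path.write_text(json.dumps(result.meta, indent=2, default=float))


def write_member(path: Path | str, member: ModelMember) -> None:
    member.data.rename_axis("year").reset_index().to_csv(path, index=False)


def read_member(path: Path | str) -> ModelMember:
    df = pd.read_csv(path)
    data = df.set_index(df["year"].astype(int)).drop(columns="year")
    return ModelMember(name=Path(path).stem, data=data)


def read_ensemble(indir: Path | str) -> list[ModelMember]:
    paths = sorted(Path(indir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no member CSVs in {indir}")
    return [read_member(p) for p in paths]


def write_grid(path: Path | str, grid: xr.Dataset) -> None:
    grid.to_netcdf(path, engine="scipy")


def read_grid(path: Path | str) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_truth(path: Path | str, truth: TruthRecord) -> None:
    payload = {}
    for key in ("land_north", "land_south", "s_true", "b_true", "o_true"):
        value = getattr(truth, key)
        if value is not None:
            payload[key] = {str(k): float(v) for k, v in value.items()}
    if truth.delta_cveg is not None:
        payload["delta_cveg"] = float(truth.delta_cveg)
    payload["seeds"] = truth.seeds
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: Path | str) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    kwargs = {}
    for key in ("land_north", "land_south", "b_true", "o_true"):
        if key in payload:
            d = payload[key]
            kwargs[key] = pd.Series(
                list(d.values()), index=pd.Index([int(k) for k in d], name="year")
            )
    if "s_true" in payload:
        kwargs["s_true"] = pd.Series(payload["s_true"])
    return TruthRecord(
        delta_cveg=payload.get("delta_cveg"),
        seeds=payload.get("seeds", {}),
        **kwargs,
    )
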