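"""Gridded-series containers and file I/O.

The world is a rectangular lattice of cells with stable integer ids assigned
row-major from the northwest corner; latitude/longitude are optional metadata,
never keys.  Two interchange encodings are supported for every gridded
series: a plain CSV long format (cell_id, year, month, value — month omitted
for yearly series) and NetCDF written through xarray.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GridSeries",
    "LandUseSeries",
    "read_grid_series",
    "write_grid_series",
    "read_landuse_series",
    "write_landuse_series",
    "write_outputs",
]


@dataclass
class GridSeries:
    """Monthly series on a grid: ``data`` has shape (n_months, n_cells)."""

    data: np.ndarray
    nrows: int
    ncols: int
    start_year: int = 2015

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.nrows * self.ncols:
            raise ValueError("data must be (n_months, nrows*ncols)")

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def n_months(self) -> int:
        return self.data.shape[0]

    def month_index(self, year: int, month: int) -> int:
        """Absolute row for calendar (year, month-1..12)."""
        idx = (year - self.start_year) * 12 + (month - 1)
        if not 0 <= idx < self.n_months:
            raise IndexError(f"({year}, {month}) outside the series")
        return idx

    def at(self, year: int, month: int) -> np.ndarray:
        return self.data[self.month_index(year, month)]

    def year_mean(self, year: int) -> np.ndarray:
        i0 = self.month_index(year, 1)
        return self.data[i0 : i0 + 12].mean(axis=0)


@dataclass
class LandUseSeries:
    """Yearly fraction of primary + secondary land: (n_years, n_cells)."""

    data: np.ndarray
    nrows: int
    ncols: int
    start_year: int = 2015

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.nrows * self.ncols:
            raise ValueError("data must be (n_years, nrows*ncols)")
        if ((self.data < 0) | (self.data > 1)).any():
            raise ValueError("land fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def at(self, year: int) -> np.ndarray:
        idx = year - self.start_year
        if not 0 <= idx < self.data.shape[0]:
            raise IndexError(f"year {year} outside the series")
        return self.data[idx]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _validate_long(df: pd.DataFrame, monthly: bool) -> None:
    cols = {"cell_id", "year", "value"} | ({"month"} if monthly else set())
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = df[~np.isfinite(df["value"].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"non-finite values at rows {bad.index[:5].tolist()}")


def read_grid_series(path, variable: str | None = None) -> GridSeries:
    """Read a monthly gridded series from CSV long format or NetCDF.

    CSV columns: cell_id, year, month, value plus optional nrows/ncols
    metadata columns (otherwise the grid is inferred as a single row of
    cells is refused — the writer always embeds nrows/ncols).  Every cell
    must cover every month of the spanned range; gaps are reported by name.
    """
    path = Path(path)
    if path.suffix in {".nc", ".cdf", ".netcdf"}:
        return _read_grid_netcdf(path, variable)
    df = pd.read_csv(path)
    _validate_long(df, monthly=True)
    if not {"nrows", "ncols"} <= set(df.columns):
        raise ValueError("CSV grid series requires nrows/ncols metadata columns")
    nrows, ncols = int(df["nrows"].iloc[0]), int(df["ncols"].iloc[0])
    n_cells = nrows * ncols
    start_year = int(df["year"].min())
    months = (df["year"] - start_year) * 12 + (df["month"] - 1)
    n_months = int(months.max()) + 1
    data = np.full((n_months, n_cells), np.nan)
    data[months.to_numpy(), df["cell_id"].to_numpy()] = df["value"].to_numpy(dtype=float)
    if np.isnan(data).any():
        m, c = np.argwhere(np.isnan(data))[0]
        y, mo = start_year + m // 12, m % 12 + 1
        raise ValueError(f"missing value for cell {c} at {y}-{mo:02d}")
    return GridSeries(data, nrows, ncols, start_year)


def write_grid_series(series: GridSeries, path, variable: str = "value") -> None:
    path = Path(path)
    if path.suffix in {".nc", ".cdf", ".netcdf"}:
        _write_grid_netcdf(series, path, variable)
        return
    n_m, n_c = series.data.shape
    months = np.repeat(np.arange(n_m), n_c)
    cells = np.tile(np.arange(n_c), n_m)
    df = pd.DataFrame(
        {
            "cell_id": cells,
            "year": series.start_year + months // 12,
            "month": months % 12 + 1,
            "value": series.data.ravel(),
            "nrows": series.nrows,
            "ncols": series.ncols,
        }
    )
    df.to_csv(path, index=False)


def _read_grid_netcdf(path: Path, variable: str | None) -> GridSeries:
    import xarray as xr

    with xr.open_dataset(path) as ds:
        name = variable or list(ds.data_vars)[0]
        da = ds[name]
        data = np.asarray(da.values, dtype=float)
        nrows, ncols = data.shape[1], data.shape[2]
        start_year = int(da.attrs.get("start_year", ds.attrs.get("start_year", 2015)))
    return GridSeries(data.reshape(data.shape[0], -1), nrows, ncols, start_year)


def _write_grid_netcdf(series: GridSeries, path: Path, variable: str) -> None:
    import xarray as xr

    da = xr.DataArray(
        series.data.reshape(series.n_months, series.nrows, series.ncols),
        dims=("time", "y", "x"),
        attrs={"start_year": series.start_year},
        name=variable,
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_landuse_series(path) -> LandUseSeries:
    df = pd.read_csv(path)
    _validate_long(df, monthly=False)
    if not {"nrows", "ncols"} <= set(df.columns):
        raise ValueError("CSV land-use series requires nrows/ncols metadata columns")
    nrows, ncols = int(df["nrows"].iloc[0]), int(df["ncols"].iloc[0])
    start_year = int(df["year"].min())
    years = df["year"] - start_year
    n_years = int(years.max()) + 1
    data = np.full((n_years, nrows * ncols), np.nan)
    data[years.to_numpy(), df["cell_id"].to_numpy()] = df["value"].to_numpy(dtype=float)
    if np.isnan(data).any():
        y, c = np.argwhere(np.isnan(data))[0]
        raise ValueError(f"missing land-use value for cell {c} in year {start_year + y}")
    return LandUseSeries(data, nrows, ncols, start_year)


def write_landuse_series(series: LandUseSeries, path) -> None:
    n_y, n_c = series.data.shape
    years = np.repeat(np.arange(n_y), n_c)
    df = pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(n_c), n_y),
            "year": series.start_year + years,
            "value": series.data.ravel(),
            "nrows": series.nrows,
            "ncols": series.ncols,
        }
    )
    df.to_csv(path, index=False)


def write_outputs(bundle: dict, outdir) -> dict:
    """Write a run bundle (metrics/events DataFrames, per-replicate webs,
    config and seeds) as tidy CSVs plus a JSON manifest; returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for key in ("metrics", "events"):
        df = bundle.get(key)
        if df is not None and len(df):
            p = outdir / f"{key}.csv"
            df.to_csv(p, index=False)
            files[key] = p.name
    for name, df in bundle.get("webs", {}).items():
        p = outdir / f"web_{name}.csv"
        df.to_csv(p, index=False)
        files[f"web_{name}"] = p.name
    config = bundle.get("config", {})
    manifest = {
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "master_seed": bundle.get("master_seed"),
        "replicate_seeds": bundle.get("replicate_seeds", []),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
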