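"""Shared spatial/tabular data model and file I/O.

All gridded quantities live on a common equal-area grid of square cells
(abstract km units, 4 km by default, mirroring a regional chemical-transport
model grid).  Daily fields are stored as ``FieldStack`` objects — a
``(day, row, col)`` array plus grid metadata and an ordered date axis.
Satellite AOD with missing pixels is a ``MaskedFieldStack``; surface
monitors, county mortality and population carry their own containers.

On disk, gridded data are NetCDF (classic format, written through xarray's
scipy backend) with dimensions ``(time, y, x)``; tables are plain CSV.
Invalid AOD pixels are stored as NaN with a companion ``<name>_valid`` byte
variable, so files remain self-describing.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FormatError, MissingDateError, ValidationError

__all__ = [
    "Grid",
    "FieldStack",
    "MaskedFieldStack",
    "MonitorTable",
    "PopulationGrid",
    "CountyRaster",
    "MortalityTable",
    "write_field_stack",
    "read_field_stack",
    "write_masked_field_stack",
    "read_masked_field_stack",
    "write_population",
    "read_population",
    "write_county_raster",
    "read_county_raster",
    "read_monitor_csv",
    "write_monitor_csv",
    "read_mortality_csv",
    "write_mortality_csv",
    "collocate",
]

_NETCDF_ENGINE = "scipy"  # classic NetCDF3; portable and dependency-light

MONITOR_COLUMNS = ["site_id", "row", "col", "date", "pm25_obs"]
MORTALITY_COLUMNS = ["county_id", "daily_deaths"]


@dataclass(frozen=True)
class Grid:
    """Regular row-major grid of square cells.

    Cell ``(i, j)`` (0-based) has its center at
    ``(x0 + (j + 0.5) * cell_size, y0 + (i + 0.5) * cell_size)``.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 4.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "synthetic-km"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValidationError(
                f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (j + 0.5) * self.cell_size, y0 + (i + 0.5) * self.cell_size)

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def _as_dates(dates: Sequence) -> tuple[dt.date, ...]:
    out = tuple(pd.Timestamp(d).date() for d in dates)
    if len(out) != len(set(out)):
        raise ValidationError("dates must be unique")
    if list(out) != sorted(out):
        raise ValidationError("dates must be ascending")
    return out


@dataclass
class FieldStack:
    """A daily gridded field: values indexed ``(day, row, col)``."""

    grid: Grid
    dates: tuple[dt.date, ...]
    values: np.ndarray
    name: str = "field"

    def __post_init__(self) -> None:
        self.dates = _as_dates(self.dates)
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.dates), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != (n_days, n_rows, n_cols) {expected}"
            )

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def day_index(self, date) -> int:
        d = pd.Timestamp(date).date()
        try:
            return self.dates.index(d)
        except ValueError:
            raise MissingDateError(
                f"date {d} not in stack '{self.name}' "
                f"(covers {self.dates[0]} .. {self.dates[-1]})"
            ) from None

    def require_nonnegative(self) -> None:
        if np.nanmin(self.values) < 0:
            raise ValidationError(f"stack '{self.name}' contains negative values")

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "FieldStack":
        return FieldStack(self.grid, self.dates, np.array(values), name or self.name)


@dataclass
class MaskedFieldStack:
    """A field stack plus a validity mask; invalid cells are never read."""

    base: FieldStack
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.base.values.shape:
            raise ValidationError("valid mask shape differs from values shape")

    @property
    def grid(self) -> Grid:
        return self.base.grid

    @property
    def dates(self) -> tuple[dt.date, ...]:
        return self.base.dates

    def missing_fraction(self) -> np.ndarray:
        """Fraction of invalid pixels, one value per day."""
        return 1.0 - self.valid.mean(axis=(1, 2))


def _validate_monitor_df(df: pd.DataFrame, grid: Grid | None) -> pd.DataFrame:
    missing = [c for c in MONITOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"monitor table missing columns: {missing}")
    df = df.loc[:, MONITOR_COLUMNS].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    df["pm25_obs"] = df["pm25_obs"].astype(float)
    dup = df.duplicated(subset=["site_id", "date"])
    if dup.any():
        bad = df.loc[dup, ["site_id", "date"]].iloc[0]
        raise ValidationError(
            f"duplicate (site_id, date) record: ({bad.site_id}, {bad.date})"
        )
    if (df["pm25_obs"] < 0).any() or not np.isfinite(df["pm25_obs"]).all():
        raise ValidationError("pm25_obs must be finite and nonnegative")
    if grid is not None and not grid.contains(df["row"], df["col"]).all():
        raise ValidationError("monitor (row, col) outside grid bounds")
    return df.reset_index(drop=True)


@dataclass
class MonitorTable:
    """Site-day records of observed surface PM2.5 pinned to host grid cells."""

    df: pd.DataFrame
    grid: Grid | None = None

    def __post_init__(self) -> None:
        self.df = _validate_monitor_df(self.df, self.grid)

    @classmethod
    def from_records(cls, records, grid: Grid | None = None) -> "MonitorTable":
        return cls(pd.DataFrame(records, columns=MONITOR_COLUMNS), grid)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.df["site_id"].unique())


@dataclass
class PopulationGrid:
    grid: Grid
    pop: np.ndarray

    def __post_init__(self) -> None:
        self.pop = np.asarray(self.pop, dtype=np.float64)
        if self.pop.shape != self.grid.shape:
            raise ValidationError("population shape differs from grid shape")
        if (self.pop < 0).any():
            raise ValidationError("population must be nonnegative")
        if self.pop.sum() <= 0:
            raise ValidationError("total population must be positive")


@dataclass
class CountyRaster:
    grid: Grid
    county_id: np.ndarray

    def __post_init__(self) -> None:
        self.county_id = np.asarray(self.county_id, dtype=np.int64)
        if self.county_id.shape != self.grid.shape:
            raise ValidationError("county raster shape differs from grid shape")

    @property
    def county_list(self) -> np.ndarray:
        return np.unique(self.county_id)


@dataclass
class MortalityTable:
    """County-level daily-average multiple-cause deaths."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MORTALITY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"mortality table missing columns: {missing}")
        df = self.df.loc[:, MORTALITY_COLUMNS].copy()
        df["county_id"] = df["county_id"].astype(int)
        df["daily_deaths"] = df["daily_deaths"].astype(float)
        if df["county_id"].duplicated().any():
            raise ValidationError("duplicate county_id in mortality table")
        if not np.isfinite(df["daily_deaths"]).all() or (df["daily_deaths"] < 0).any():
            raise ValidationError("daily_deaths must be finite and nonnegative")
        self.df = df.reset_index(drop=True)

    def deaths_by_county(self) -> dict[int, float]:
        return dict(zip(self.df["county_id"], self.df["daily_deaths"]))


# ---------------------------------------------------------------------------
# NetCDF I/O


def _grid_attrs(grid: Grid) -> dict:
    return {
        "cell_size": float(grid.cell_size),
        "origin_x": float(grid.origin[0]),
        "origin_y": float(grid.origin[1]),
        "crs_label": grid.crs_label,
    }


def _grid_from_ds(ds: xr.Dataset) -> Grid:
    return Grid(
        n_rows=ds.sizes["y"],
        n_cols=ds.sizes["x"],
        cell_size=float(ds.attrs.get("cell_size", 4.0)),
        origin=(float(ds.attrs.get("origin_x", 0.0)), float(ds.attrs.get("origin_y", 0.0))),
        crs_label=str(ds.attrs.get("crs_label", "synthetic-km")),
    )


def _check_dims(ds: xr.Dataset, required: tuple[str, ...], path) -> None:
    for dim in required:
        if dim not in ds.sizes:
            raise FormatError(f"{path}: missing required dimension '{dim}'")


def write_field_stack(stack: FieldStack, path) -> None:
    da = xr.DataArray(
        stack.values,
        dims=("time", "y", "x"),
        coords={"time": pd.to_datetime(list(stack.dates))},
        name=stack.name or "field",
    )
    ds = da.to_dataset()
    ds.attrs.update(_grid_attrs(stack.grid))
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


def read_field_stack(path, name: str | None = None) -> FieldStack:
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        ds = ds.load()
    _check_dims(ds, ("time", "y", "x"), path)
    if name is None:
        candidates = [
            v
            for v in ds.data_vars
            if ds[v].dims == ("time", "y", "x") and not str(v).endswith("_valid")
        ]
        if not candidates:
            raise FormatError(f"{path}: no (time, y, x) data variable found")
        name = str(candidates[0])
    elif name not in ds.data_vars:
        raise FormatError(f"{path}: variable '{name}' not present")
    dates = [pd.Timestamp(t).date() for t in ds["time"].values]
    return FieldStack(_grid_from_ds(ds), tuple(dates), ds[name].values, str(name))


def write_masked_field_stack(mstack: MaskedFieldStack, path) -> None:
    name = mstack.base.name or "field"
    vals = mstack.base.values.copy()
    vals[~mstack.valid] = np.nan  # NaN sentinel at invalid pixels
    ds = xr.Dataset(
        {
            name: (("time", "y", "x"), vals),
            f"{name}_valid": (("time", "y", "x"), mstack.valid.astype(np.int8)),
        },
        coords={"time": pd.to_datetime(list(mstack.base.dates))},
    )
    ds.attrs.update(_grid_attrs(mstack.base.grid))
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


def read_masked_field_stack(path, name: str | None = None) -> MaskedFieldStack:
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        ds = ds.load()
    _check_dims(ds, ("time", "y", "x"), path)
    if name is None:
        candidates = [v for v in ds.data_vars if str(v).endswith("_valid")]
        if not candidates:
            raise FormatError(f"{path}: no '<name>_valid' mask variable found")
        name = str(candidates[0])[: -len("_valid")]
    mask_var = f"{name}_valid"
    if name not in ds.data_vars or mask_var not in ds.data_vars:
        raise FormatError(f"{path}: expected variables '{name}' and '{mask_var}'")
    valid = ds[mask_var].values.astype(bool)
    vals = ds[name].values.copy()
    vals[~valid] = np.nan
    dates = [pd.Timestamp(t).date() for t in ds["time"].values]
    base = FieldStack(_grid_from_ds(ds), tuple(dates), vals, str(name))
    return MaskedFieldStack(base, valid)


def write_population(pop: PopulationGrid, path) -> None:
    ds = xr.Dataset({"population": (("y", "x"), pop.pop)})
    ds.attrs.update(_grid_attrs(pop.grid))
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


def read_population(path) -> PopulationGrid:
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        ds = ds.load()
    _check_dims(ds, ("y", "x"), path)
    if "population" not in ds.data_vars:
        raise FormatError(f"{path}: variable 'population' not present")
    return PopulationGrid(_grid_from_ds(ds), ds["population"].values)


def write_county_raster(counties: CountyRaster, path) -> None:
    ds = xr.Dataset({"county_id": (("y", "x"), counties.county_id.astype(np.int32))})
    ds.attrs.update(_grid_attrs(counties.grid))
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


def read_county_raster(path) -> CountyRaster:
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        ds = ds.load()
    _check_dims(ds, ("y", "x"), path)
    if "county_id" not in ds.data_vars:
        raise FormatError(f"{path}: variable 'county_id' not present")
    return CountyRaster(_grid_from_ds(ds), ds["county_id"].values.astype(np.int64))


# ---------------------------------------------------------------------------
# CSV I/O


def read_monitor_csv(path, grid: Grid | None = None) -> MonitorTable:
    df = pd.read_csv(path, dtype={"site_id": str}, float_precision="round_trip")
    return MonitorTable(df, grid)


def write_monitor_csv(table: MonitorTable, path) -> None:
    out = table.df.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_mortality_csv(path) -> MortalityTable:
    return MortalityTable(pd.read_csv(path, float_precision="round_trip"))


def write_mortality_csv(table: MortalityTable, path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Collocation


def collocate(table: MonitorTable, stack: FieldStack) -> pd.DataFrame:
    """Pair each monitor record with the stack value at its host cell and day.

    Returns one row per input record with columns
    ``site_id, row, col, date, pm25_obs, field_value``.
    """
    df = table.df
    if not stack.grid.contains(df["row"], df["col"]).all():
        raise ValidationError("monitor (row, col) outside stack grid")
    date_index = {d: i for i, d in enumerate(stack.dates)}
    missing = sorted({d for d in df["date"] if d not in date_index})
    if missing:
        raise MissingDateError(
            f"monitor dates not covered by stack '{stack.name}': "
            f"{[d.isoformat() for d in missing]}"
        )
    day_idx = df["date"].map(date_index).to_numpy()
    values = stack.values[day_idx, df["row"].to_numpy(), df["col"].to_numpy()]
    out = df.copy()
    out["field_value"] = values
    return out
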