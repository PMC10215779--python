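"""Gridded monthly ocean climatology container.

The analysis pairs jellyfish occurrence reports against monthly
climatological means of seven ocean variables (temperature, salinity,
dissolved oxygen, percent oxygen saturation, silicate, phosphate,
nitrate) at four shallow depths (0, 5, 10, 20 m) — 28 predictors per
location/month.  :class:`EnvFieldSet` wraps an :class:`xarray.Dataset`
with dims ``(month, depth, lat, lon)`` and one data variable per ocean
variable.  Land is encoded as NaN and shared across all slices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

VARIABLES: tuple[str, ...] = (
    "temperature",
    "salinity",
    "dissolved_oxygen",
    "oxygen_saturation",
    "silicate",
    "phosphate",
    "nitrate",
)

DEPTHS: tuple[int, ...] = (0, 5, 10, 20)

#: Canonical predictor order: variables in WOA order, each at 0/5/10/20 m.
PREDICTORS: tuple[str, ...] = tuple(
    f"{v}_{d}m" for v in VARIABLES for d in DEPTHS
)


def predictor_id(variable: str, depth: int) -> str:
    """Canonical column name for a (variable, depth) pair, e.g. ``temperature_20m``."""
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if depth not in DEPTHS:
        raise ValueError(f"unknown depth {depth!r}")
    return f"{variable}_{depth}m"


def split_predictor(pid: str) -> tuple[str, int]:
    """Inverse of :func:`predictor_id`."""
    stem, _, dpart = pid.rpartition("_")
    if stem not in VARIABLES or not dpart.endswith("m"):
        raise ValueError(f"not a predictor id: {pid!r}")
    depth = int(dpart[:-1])
    if depth not in DEPTHS:
        raise ValueError(f"not a predictor id: {pid!r}")
    return stem, depth


@dataclasses.dataclass
class EnvFieldSet:
    """Monthly gridded climatology: 7 variables x 4 depths on a lat/lon grid.

    Parameters
    ----------
    ds
        Dataset with data variables :data:`VARIABLES`, dims
        ``(month, depth, lat, lon)``.  ``lat``/``lon`` hold cell-center
        coordinates of a regular grid; NaN marks land (shared mask).
    """

    ds: xr.Dataset

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry ---------------------------------------------------------

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def months(self) -> np.ndarray:
        return self.ds["month"].values

    @property
    def resolution(self) -> float:
        """Grid step in degrees (identical for lat and lon)."""
        return float(self.ds.attrs["resolution"])

    @property
    def ocean_mask(self) -> np.ndarray:
        """Boolean (lat, lon) grid, True where ocean (non-missing)."""
        first = self.ds[VARIABLES[0]].isel(month=0, depth=0).values
        return np.isfinite(first)

    def validate(self) -> None:
        missing = [v for v in VARIABLES if v not in self.ds.data_vars]
        if missing:
            raise ValueError(f"climatology missing variables: {missing}")
        for v in VARIABLES:
            if self.ds[v].dims != ("month", "depth", "lat", "lon"):
                raise ValueError(
                    f"{v} has dims {self.ds[v].dims}, expected (month, depth, lat, lon)"
                )
        # the land mask must be shared by every variable/depth/month slice
        mask = self.ocean_mask
        for v in VARIABLES:
            finite = np.isfinite(self.ds[v].values)
            if not (finite == mask[None, None, :, :]).all():
                raise ValueError(f"{v} does not share the common land mask")

    # -- access -----------------------------------------------------------

    def values(self) -> np.ndarray:
        """All fields as one array shaped (variable, month, depth, lat, lon)."""
        return np.stack([self.ds[v].values for v in VARIABLES])

    def predictor_cube(self, pid: str) -> np.ndarray:
        """A predictor's (month, lat, lon) cube."""
        var, depth = split_predictor(pid)
        return self.ds[var].sel(depth=depth).values

    def predictor_grid(self, pid: str, month: int) -> np.ndarray:
        """A predictor's (lat, lon) grid for one calendar month."""
        var, depth = split_predictor(pid)
        return self.ds[var].sel(depth=depth, month=month).values

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Indices of the grid cell containing a point (lon wraps)."""
        step = self.resolution
        i = int(np.clip(np.floor((lat + 90.0) / step), 0, len(self.lats) - 1))
        j = int(np.floor(((lon + 180.0) % 360.0) / step)) % len(self.lons)
        return i, j

    # -- I/O ----------------------------------------------------------------

    def to_netcdf(self, directory: str | Path) -> list[Path]:
        """Write one NetCDF (classic format) file per variable."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for v in VARIABLES:
            p = directory / f"{v}.nc"
            one = self.ds[[v]]
            one.attrs = dict(self.ds.attrs)
            one.to_netcdf(p, engine="scipy")
            paths.append(p)
        return paths

    @classmethod
    def from_netcdf(cls, directory: str | Path) -> "EnvFieldSet":
        directory = Path(directory)
        parts = []
        for v in VARIABLES:
            p = directory / f"{v}.nc"
            if not p.exists():
                raise FileNotFoundError(f"missing climatology file: {p}")
            with xr.open_dataset(p, engine="scipy") as one:
                parts.append(one.load())
        ds = xr.merge(parts, combine_attrs="override")
        ds.attrs = dict(parts[0].attrs)
        return cls(ds)

    def to_long_csv(self, path: str | Path) -> Path:
        """Long-format CSV dialect: variable,depth,month,lat,lon,value (ocean cells)."""
        path = Path(path)
        frames = []
        for v in VARIABLES:
            df = self.ds[v].to_dataframe(name="value").reset_index()
            df.insert(0, "variable", v)
            frames.append(df[np.isfinite(df["value"])])
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_long_csv(cls, path: str | Path, resolution: float) -> "EnvFieldSet":
        df = pd.read_csv(path)
        need = {"variable", "depth", "month", "lat", "lon", "value"}
        if not need.issubset(df.columns):
            raise ValueError(f"long CSV missing columns: {sorted(need - set(df.columns))}")
        months = np.sort(df["month"].unique())
        lats = grid_centers(-90.0, 90.0, resolution)
        lons = grid_centers(-180.0, 180.0, resolution)
        data = {}
        for v in VARIABLES:
            cube = np.full((len(months), len(DEPTHS), len(lats), len(lons)), np.nan)
            sub = df[df["variable"] == v]
            mi = np.searchsorted(months, sub["month"].values)
            di = np.searchsorted(np.asarray(DEPTHS), sub["depth"].values)
            li = np.searchsorted(lats, sub["lat"].values)
            ji = np.searchsorted(lons, sub["lon"].values)
            cube[mi, di, li, ji] = sub["value"].values
            data[v] = (("month", "depth", "lat", "lon"), cube)
        ds = xr.Dataset(
            data,
            coords={"month": months, "depth": list(DEPTHS), "lat": lats, "lon": lons},
            attrs={"resolution": resolution},
        )
        return cls(ds)


def grid_centers(lo: float, hi: float, step: float) -> np.ndarray:
    """Cell-center coordinates of a regular grid over [lo, hi]."""
    n = int(round((hi - lo) / step))
    return lo + step * (np.arange(n) + 0.5)


def build_dataset(
    cubes: dict[str, np.ndarray],
    lats: np.ndarray,
    lons: np.ndarray,
    months: Sequence[int],
    resolution: float,
) -> EnvFieldSet:
    """Assemble an :class:`EnvFieldSet` from (month, depth, lat, lon) arrays."""
    ds = xr.Dataset(
        {v: (("month", "depth", "lat", "lon"), cubes[v]) for v in VARIABLES},
        coords={
            "month": list(months),
            "depth": list(DEPTHS),
            "lat": lats,
            "lon": lons,
        },
        attrs={"resolution": float(resolution)},
    )
    return EnvFieldSet(ds)
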