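"""Report-to-climatology pairing and the curated modelling frame.

Each report is paired with every climatology grid cell whose center lies
within ±window degrees of the report in both latitude and longitude
(longitude wraps across the date line; latitude clamps at the poles) in
the report's calendar month; all matches are averaged per (variable,
depth), giving a 28-value environmental profile.  Reports are then
snapped to a coarser mapping grid (1 or 2 degrees) and accumulated into
the curated multivariate abundance and environmental dataframe: one row
per occupied cell (x month), genus counts plus the averaged profile.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fields import PREDICTORS, VARIABLES, DEPTHS, EnvFieldSet
from .ingest import Report

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EnvironmentalProfile:
    """28 paired (variable, depth) means plus per-entry matched-cell counts."""

    values: dict[str, float]
    n_cells: dict[str, int]

    @property
    def unpairable(self) -> bool:
        return all(n == 0 for n in self.n_cells.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.values[p] for p in PREDICTORS])


@dataclasses.dataclass
class CuratedFrame:
    """Curated multivariate abundance + environment dataframe.

    ``df`` columns: ``lat, lon[, month]``, one count column per genus,
    then the 28 predictor columns in canonical order.
    """

    df: pd.DataFrame
    genera: tuple[str, ...]
    map_step: float
    window: float
    n_unpairable: int = 0

    @property
    def predictors(self) -> tuple[str, ...]:
        return PREDICTORS

    def counts(self) -> pd.DataFrame:
        return self.df[list(self.genera)]

    def profiles(self) -> pd.DataFrame:
        return self.df[list(PREDICTORS)]


def pair_report(
    report: Report, env: EnvFieldSet, window: float = 2.0
) -> EnvironmentalProfile:
    """Average all climatology cells within ±window degrees, same month.

    An entry is missing (NaN, n_cells 0) only when every grid cell in the
    window is land for that (variable, depth); with a shared land mask
    this happens for all 28 entries at once and the report is flagged
    unpairable.
    """
    if report.month is None:
        raise ValueError(f"report {report.report_id} has no month; cannot pair")
    if report.month not in set(int(m) for m in env.months):
        raise ValueError(f"month {report.month} not present in climatology")
    lat_sel = np.abs(env.lats - report.latitude) <= window
    dlon = (env.lons - report.longitude + 180.0) % 360.0 - 180.0
    lon_sel = np.abs(dlon) <= window
    values: dict[str, float] = {}
    n_cells: dict[str, int] = {}
    # (var, depth, lat, lon) block for the report's month
    block = env.ds.sel(month=report.month)
    for v in VARIABLES:
        sub = block[v].values[:, lat_sel][:, :, lon_sel]  # (depth, k1, k2)
        for di, d in enumerate(DEPTHS):
            pid = f"{v}_{d}m"
            vals = sub[di]
            finite = np.isfinite(vals)
            n = int(finite.sum())
            n_cells[pid] = n
            values[pid] = float(vals[finite].mean()) if n else float("nan")
    return EnvironmentalProfile(values=values, n_cells=n_cells)


class _PairingCache:
    """Vectorized batch pairing with memoization on (lat, lon, month)."""

    def __init__(self, env: EnvFieldSet, window: float):
        self.env = env
        self.window = window
        # env.values() is (var, month, depth, lat, lon) -> (month, lat, lon, var, depth)
        self.arr = np.transpose(env.values(), (1, 3, 4, 0, 2))
        self.month_index = {int(m): i for i, m in enumerate(env.months)}
        self._memo: dict[tuple[float, float, int], np.ndarray] = {}

    def profile(self, report: Report) -> np.ndarray:
        if report.month is None:
            raise ValueError(f"report {report.report_id} has no month; cannot pair")
        key = (report.latitude, report.longitude, report.month)
        got = self._memo.get(key)
        if got is not None:
            return got
        env = self.env
        lat_sel = np.abs(env.lats - report.latitude) <= self.window
        dlon = (env.lons - report.longitude + 180.0) % 360.0 - 180.0
        lon_sel = np.abs(dlon) <= self.window
        mi = self.month_index[report.month]
        sub = self.arr[mi][lat_sel][:, lon_sel]  # (k1, k2, var, depth)
        with np.errstate(invalid="ignore"):
            prof = np.nanmean(sub.reshape(-1, len(VARIABLES) * len(DEPTHS)), axis=0)
        self._memo[key] = prof
        return prof


def snap_to_cell(lat: float, lon: float, step: float) -> tuple[float, float]:
    """Map a coordinate to the center of its ``step``-degree mapping cell."""
    i = np.floor((lat + 90.0) / step)
    i = min(i, 180.0 / step - 1)  # lat == 90 belongs to the last row
    j = np.floor(((lon + 180.0) % 360.0) / step)
    return (-90.0 + (i + 0.5) * step, -180.0 + (j + 0.5) * step)


def build_frame(
    reports: Iterable[Report],
    env: EnvFieldSet,
    map_step: float = 2.0,
    window: float = 2.0,
    collapse_months: bool = False,
    genera: Sequence[str] | None = None,
) -> CuratedFrame:
    """Assemble the curated frame from pairable reports.

    Reports are snapped to ``map_step``-degree cells; genus counts are
    accumulated per cell (x month unless ``collapse_months``), and each
    row's profile is the mean over its member reports' profiles (an entry
    is missing only if missing for every member).  Unpairable reports
    (all 28 entries missing) are excluded and counted.
    """
    if map_step <= 0:
        raise ValueError("map_step must be positive")
    reports = list(reports)
    if genera is None:
        seen: list[str] = []
        for r in reports:
            if r.genus not in seen:
                seen.append(r.genus)
        genera = seen
    genera = tuple(genera)

    cache = _PairingCache(env, window)
    rows: dict[tuple, dict] = {}
    n_unpairable = 0
    for r in reports:
        prof = cache.profile(r)
        if not np.isfinite(prof).any():
            n_unpairable += 1
            continue
        cell = snap_to_cell(r.latitude, r.longitude, map_step)
        key = cell if collapse_months else (*cell, r.month)
        slot = rows.get(key)
        if slot is None:
            slot = rows[key] = {
                "counts": dict.fromkeys(genera, 0),
                "profs": [],
            }
        if r.genus in slot["counts"]:
            slot["counts"][r.genus] += 1
        else:  # genus outside the configured set still occupies the row
            slot["counts"][r.genus] = 1
        slot["profs"].append(prof)

    records = []
    for key in sorted(rows):
        slot = rows[key]
        stack = np.vstack(slot["profs"])
        with np.errstate(invalid="ignore"):
            prof = np.nanmean(stack, axis=0)
        rec: dict = {"lat": key[0], "lon": key[1]}
        if not collapse_months:
            rec["month"] = key[2]
        for g in genera:
            rec[g] = slot["counts"].get(g, 0)
        for p, val in zip(PREDICTORS, prof):
            rec[p] = val
        records.append(rec)

    cols = ["lat", "lon"] + ([] if collapse_months else ["month"]) + list(genera) + list(PREDICTORS)
    df = pd.DataFrame(records, columns=cols)
    if len(df):
        # CuratedFrame invariant: every row has at least one positive count
        assert (df[list(genera)].sum(axis=1) > 0).all()
    logger.info("curated frame: %d rows from %d reports (%d unpairable)",
                len(df), len(reports), n_unpairable)
    return CuratedFrame(df=df, genera=genera, map_step=map_step,
                        window=window, n_unpairable=n_unpairable)


def frame_from_csv(path, map_step: float = 2.0, window: float = 2.0) -> CuratedFrame:
    """Rebuild a CuratedFrame from a ``build_frame`` CSV export."""
    df = pd.read_csv(path)
    meta = {"lat", "lon", "month"}
    genera = tuple(c for c in df.columns if c not in meta and c not in PREDICTORS)
    missing = [p for p in PREDICTORS if p not in df.columns]
    if missing:
        raise ValueError(f"frame CSV missing predictor columns: {missing[:3]}...")
    return CuratedFrame(df=df, genera=genera, map_step=map_step, window=window)


def impute_for_model(
    frame: CuratedFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute missing predictor entries for model fitting.

    Returns the imputed predictor block and a boolean audit table marking
    which entries were imputed.  Only model fitting sees imputed values;
    the curated frame itself is never altered.
    """
    X = frame.profiles().copy()
    audit = X.isna()
    med = X.median()
    X = X.fillna(med)
    if X.isna().any().any():  # a column with no observed values at all
        bad = [c for c in X.columns if X[c].isna().any()]
        raise ValueError(f"predictors with no observed values: {bad}")
    return X, audit
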