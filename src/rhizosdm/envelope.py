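"""Percentile-envelope habitat prediction and 2D density rendering.

Suitable habitat for a genus is the rectangular environmental envelope
spanned by the central 90% interval (5th–95th percentile, linear
interpolation) of each selected predictor among positive profiles.  A
grid cell is predicted suitable when every selected predictor at that
cell falls within its bounds — in any month by default, or per month.
Predicted cells are rendered as a Gaussian kernel density on the
lat/lon plane for mapping.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fields import EnvFieldSet


@dataclasses.dataclass
class Envelope:
    """Per selected predictor, the (lower, upper) suitability bounds."""

    genus: str
    bounds: dict[str, tuple[float, float]]
    central_fraction: float = 0.90

    def __post_init__(self) -> None:
        for pid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"lower > upper for {pid}")


@dataclasses.dataclass
class SuitabilityMap:
    """Predicted suitable cells (+ optional per-month masks and density)."""

    genus: str
    mask: np.ndarray                       # (lat, lon) bool, any-month
    lats: np.ndarray
    lons: np.ndarray
    month_mode: str = "any_month"
    per_month: Optional[np.ndarray] = None  # (month, lat, lon) bool
    density: Optional[np.ndarray] = None
    ocean: Optional[np.ndarray] = None

    @property
    def suitable_cells(self) -> set[tuple[float, float]]:
        ii, jj = np.where(self.mask)
        return {(float(self.lats[i]), float(self.lons[j])) for i, j in zip(ii, jj)}

    def area_fraction(self) -> float:
        """Fraction of ocean cells predicted suitable."""
        if self.ocean is None:
            return float(self.mask.mean())
        n_ocean = int(self.ocean.sum())
        return float(self.mask.sum() / n_ocean) if n_ocean else 0.0


def build_envelope(
    positive_profiles: pd.DataFrame,
    selected: Sequence[str],
    central_fraction: float = 0.90,
    genus: str = "",
) -> Envelope:
    """Central-``central_fraction`` percentile bounds per selected predictor.

    Quantiles use linear interpolation between order statistics.  At
    ``central_fraction=0.90`` the bounds are the 5th and 95th
    percentiles; at 1.0 they degenerate to (min, max).
    """
    if not 0.0 < central_fraction <= 1.0:
        raise ValueError("central_fraction must be in (0, 1]")
    if len(positive_profiles) < 2:
        raise ValueError("need at least 2 positive profiles")
    lo_q = (1.0 - central_fraction) / 2.0
    hi_q = (1.0 + central_fraction) / 2.0
    bounds: dict[str, tuple[float, float]] = {}
    for pid in selected:
        if pid not in positive_profiles.columns:
            raise ValueError(f"selected predictor missing from profiles: {pid}")
        vals = positive_profiles[pid].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"no finite values among positives for {pid}")
        lo = float(np.quantile(vals, lo_q, method="linear"))
        hi = float(np.quantile(vals, hi_q, method="linear"))
        bounds[pid] = (lo, hi)
    return Envelope(genus=genus, bounds=bounds, central_fraction=central_fraction)


def predict_suitable(
    env: EnvFieldSet,
    envelope: Envelope,
    month_mode: str = "any_month",
) -> SuitabilityMap:
    """Cells whose selected predictors all fall inside the envelope.

    ``any_month``: suitable if some month satisfies every bound jointly.
    ``per_month``: per-month masks are kept alongside their union.  Land
    cells are never suitable (NaN fails every comparison).
    """
    if month_mode not in ("any_month", "per_month"):
        raise ValueError(f"unknown month_mode: {month_mode}")
    months = env.months
    nlat, nlon = len(env.lats), len(env.lons)
    per_month = np.ones((len(months), nlat, nlon), dtype=bool)
    for pid, (lo, hi) in envelope.bounds.items():
        cube = env.predictor_cube(pid)  # (month, lat, lon)
        with np.errstate(invalid="ignore"):
            per_month &= (cube >= lo) & (cube <= hi)
    mask = per_month.any(axis=0)
    return SuitabilityMap(
        genus=envelope.genus,
        mask=mask,
        lats=env.lats,
        lons=env.lons,
        month_mode=month_mode,
        per_month=per_month if month_mode == "per_month" else None,
        ocean=env.ocean_mask,
    )


def density_surface(
    points: np.ndarray | Sequence[tuple[float, float]],
    lats: np.ndarray,
    lons: np.ndarray,
    bandwidth: Optional[float] = None,
) -> np.ndarray:
    """Isotropic Gaussian kernel density of (lat, lon) points on a grid.

    The surface is normalized so that ``sum(density) * cell_area == 1``
    over the grid.  Default bandwidth is a Scott-style rule,
    ``n^(-1/6)`` times the mean coordinate spread (floored at one grid
    step so single points and zero-variance clusters stay well defined —
    the reason this is not scipy's ``gaussian_kde``).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no points to estimate a density from")
    step = float(lats[1] - lats[0]) if len(lats) > 1 else 1.0
    if bandwidth is None:
        spread = 0.5 * (pts[:, 0].std() + pts[:, 1].std())
        bandwidth = max(spread * len(pts) ** (-1.0 / 6.0), step)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    dens = np.zeros_like(glat, dtype=float)
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for lat0, lon0 in pts:
        dlon = (glon - lon0 + 180.0) % 360.0 - 180.0   # wrap the date line
        dens += np.exp(-((glat - lat0) ** 2 + dlon**2) * inv2h2)
    cell_area = step * step
    total = dens.sum() * cell_area
    return dens / total if total > 0 else dens
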