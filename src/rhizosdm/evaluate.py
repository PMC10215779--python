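"""Scoring predicted distributions against independent legacy records.

The accuracy metric is percent overlap: the number of legacy reports
whose grid cell is predicted suitable, divided by the genus' total
legacy reports, times 100.  Because a near-global envelope trivially
scores high, the suitable-ocean-area fraction is reported alongside and
genera above a configurable fraction are flagged as inflation-prone.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .envelope import SuitabilityMap
from .ingest import Report


@dataclasses.dataclass(frozen=True)
class DistributionAccuracy:
    genus: str
    n_legacy: int
    n_inside: int
    accuracy_pct: float   # 100 * n_inside / n_legacy, rounded to 0.1


def _cell_index(lat: float, lon: float, lats: np.ndarray, lons: np.ndarray) -> tuple[int, int]:
    step = float(lats[1] - lats[0]) if len(lats) > 1 else 180.0
    i = int(np.clip(np.floor((lat + 90.0) / step), 0, len(lats) - 1))
    j = int(np.floor(((lon + 180.0) % 360.0) / step)) % len(lons)
    return i, j


def hdr_mask(density: np.ndarray, fraction: float = 0.95) -> np.ndarray:
    """Highest-density region: the smallest cell set holding ``fraction`` mass."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    total = csum[-1]
    if total <= 0:
        return np.zeros_like(density, dtype=bool)
    k = int(np.searchsorted(csum, fraction * total)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(density.shape)


def legacy_accuracy(
    suitability: SuitabilityMap,
    legacy_reports: Iterable[Report],
    tolerance_cells: int = 0,
    inclusion_rule: str = "mask",
    hdr_fraction: float = 0.95,
) -> DistributionAccuracy:
    """Percent of legacy reports falling inside the predicted distribution.

    With ``inclusion_rule="mask"`` (default) a report is inside when its
    containing grid cell — or any cell within ``tolerance_cells``
    (Chebyshev distance, longitude wrapping) — is suitable.  With
    ``"density"`` the predicted distribution is instead the
    ``hdr_fraction`` highest-density region of the map's density surface
    (a sensitivity option: no density cut level is canonical).
    """
    reports = list(legacy_reports)
    if not reports:
        raise ValueError("no legacy data for genus")
    genus = reports[0].genus
    if inclusion_rule == "mask":
        mask = suitability.mask
    elif inclusion_rule == "density":
        if suitability.density is None:
            raise ValueError("suitability map carries no density surface")
        mask = hdr_mask(suitability.density, hdr_fraction)
    else:
        raise ValueError(f"unknown inclusion_rule: {inclusion_rule}")
    nlat, nlon = mask.shape
    inside = 0
    for r in reports:
        i, j = _cell_index(r.latitude, r.longitude, suitability.lats, suitability.lons)
        if tolerance_cells == 0:
            hit = bool(mask[i, j])
        else:
            t = tolerance_cells
            rows = np.arange(max(0, i - t), min(nlat, i + t + 1))
            cols = (np.arange(j - t, j + t + 1)) % nlon
            hit = bool(mask[np.ix_(rows, cols)].any())
        inside += hit
    pct = round(100.0 * inside / len(reports), 1)
    return DistributionAccuracy(genus=genus, n_legacy=len(reports),
                                n_inside=inside, accuracy_pct=pct)


def accuracy_report(
    accuracies: Sequence[DistributionAccuracy],
    area_fractions: dict[str, float],
    flag_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-genus accuracy table with an inflation flag.

    ``area_fractions`` gives each genus' suitable-ocean-area fraction;
    genera whose predicted distribution covers more than
    ``flag_threshold`` of the ocean are flagged — overlap accuracy is
    cheap to earn with a near-global envelope.  Summary rows carry the
    min and max accuracy.
    """
    if not accuracies:
        raise ValueError("nothing to report")
    rows = []
    for a in accuracies:
        frac = area_fractions.get(a.genus, float("nan"))
        rows.append({
            "genus": a.genus,
            "n_legacy": a.n_legacy,
            "n_inside": a.n_inside,
            "accuracy_pct": a.accuracy_pct,
            "area_fraction": frac,
            "flag": bool(frac > flag_threshold) if np.isfinite(frac) else False,
        })
    df = pd.DataFrame(rows)
    df.attrs["accuracy_min"] = float(df["accuracy_pct"].min())
    df.attrs["accuracy_max"] = float(df["accuracy_pct"].max())
    return df
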