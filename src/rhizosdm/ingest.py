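"""Reading, validating and normalizing occurrence tables.

Two sources are supported: citizen-science exports in the iNaturalist
style (``taxon_name, latitude, longitude, observed_on``) and legacy
literature records (``genus, species, region, latitude, longitude,
reference, year``).  All reports are treated at genus rank — species
identification from photographs is unreliable for rhizostome
jellyfishes, so the genus is the first whitespace-delimited token of
the taxon string.
"""

from __future__ import annotations

import dataclasses
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The ten rhizostome genera retained by default.
DEFAULT_GENERA: tuple[str, ...] = (
    "Cassiopea",
    "Catostylus",
    "Cotylorhiza",
    "Eupilema",
    "Lobonema",
    "Lychnorhiza",
    "Pseudorhiza",
    "Rhizostoma",
    "Rhopilema",
    "Stomolophus",
)

SOURCES = ("inaturalist", "legacy")

#: Default column mappings per source.
INAT_COLUMNS: dict[str, str] = {
    "taxon": "taxon_name",
    "latitude": "latitude",
    "longitude": "longitude",
    "date": "observed_on",
    "id": "id",
}
LEGACY_COLUMNS: dict[str, str] = {
    "taxon": "genus",
    "latitude": "latitude",
    "longitude": "longitude",
    "year": "year",
    "month": "month",  # optional extension; absent in most literature tables
}


@dataclasses.dataclass(frozen=True)
class Report:
    """One genus-level occurrence record.

    ``month`` is required for citizen-science reports (environmental
    pairing is month-specific) but may be absent for legacy literature
    records, which are only scored against month-collapsed maps.
    """

    report_id: str
    genus: str
    latitude: float
    longitude: float
    month: Optional[int]
    year: Optional[int] = None
    source: str = "inaturalist"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source: {self.source}")


@dataclasses.dataclass(frozen=True)
class GenusWhitelist:
    """Ordered set of genus labels accepted by the analysis."""

    genera: tuple[str, ...] = DEFAULT_GENERA

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError("whitelist must be non-empty")
        if len(set(g.lower() for g in self.genera)) != len(self.genera):
            raise ValueError("whitelist labels must be unique")

    def normalize(self, label: str) -> Optional[str]:
        """Map a label onto its canonical whitelist spelling (case-insensitive)."""
        key = label.strip().lower()
        for g in self.genera:
            if g.lower() == key:
                return g
        return None


def genus_from_taxon(taxon: str) -> str:
    """Genus = first whitespace-delimited token of the scientific name."""
    return str(taxon).strip().split()[0]


def round_half_away(x: float, digits: int = 1) -> float:
    # Decimal on repr() avoids binary-float artefacts like 0.15*10 == 1.4999...
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_coordinate(lat: float, lon: float, digits: int = 1) -> tuple[float, float]:
    """Deterministic round-half-away-from-zero of a coordinate pair.

    Reports are aggregated per rounded coordinate; half-even (banker's)
    rounding would split ties platform-dependently, so the rule is pinned.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude out of range: {lat}")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude out of range: {lon}")
    return round_half_away(lat, digits), round_half_away(lon, digits)


def round_reports(reports: Iterable[Report], digits: int = 1) -> list[Report]:
    """Return copies of ``reports`` with coordinates rounded to ``digits``."""
    out = []
    for r in reports:
        lat, lon = round_coordinate(r.latitude, r.longitude, digits)
        out.append(dataclasses.replace(r, latitude=lat, longitude=lon))
    return out


def read_reports(
    path: str | Path,
    source: str,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[Report], pd.DataFrame]:
    """Read an occurrence CSV, returning accepted reports and a rejection log.

    Rows with missing or out-of-range coordinates, or (for the
    citizen-science source) unparseable observation dates, are rejected
    with a reason; ``len(rows) == len(accepted) + len(rejected)`` always.

    Raises
    ------
    ValueError
        If a mandatory column is absent (the error names the column).
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source: {source}")
    cols = dict(INAT_COLUMNS if source == "inaturalist" else LEGACY_COLUMNS)
    if columns:
        cols.update(columns)

    df = pd.read_csv(path)
    mandatory = ["taxon", "latitude", "longitude"]
    if source == "inaturalist":
        mandatory.append("date")
    for key in mandatory:
        if cols[key] not in df.columns:
            raise ValueError(f"missing mandatory column: {cols[key]!r} (role: {key})")

    months = pd.Series([pd.NA] * len(df))
    years = pd.Series([pd.NA] * len(df))
    if source == "inaturalist":
        when = pd.to_datetime(df[cols["date"]], errors="coerce")
        months = when.dt.month
        years = when.dt.year
    else:
        if cols.get("month") in df.columns:
            months = pd.to_numeric(df[cols["month"]], errors="coerce")
        if cols.get("year") in df.columns:
            years = pd.to_numeric(df[cols["year"]], errors="coerce")

    lat = pd.to_numeric(df[cols["latitude"]], errors="coerce")
    lon = pd.to_numeric(df[cols["longitude"]], errors="coerce")

    accepted: list[Report] = []
    rejected: list[dict] = []
    for i in range(len(df)):
        taxon = df[cols["taxon"]].iloc[i]
        reason = None
        if pd.isna(taxon) or not str(taxon).strip():
            reason = "missing taxon"
        elif pd.isna(lat.iloc[i]):
            reason = "missing latitude"
        elif not -90.0 <= lat.iloc[i] <= 90.0:
            reason = "latitude out of range"
        elif pd.isna(lon.iloc[i]):
            reason = "missing longitude"
        elif not -180.0 <= lon.iloc[i] <= 180.0:
            reason = "longitude out of range"
        elif source == "inaturalist" and pd.isna(months.iloc[i]):
            reason = "unparseable date"
        if reason is not None:
            rejected.append({"row": i, "reason": reason})
            continue
        rid = (
            str(df[cols["id"]].iloc[i])
            if cols.get("id") in df.columns
            else f"{source}-{i}"
        )
        accepted.append(
            Report(
                report_id=rid,
                genus=genus_from_taxon(taxon),
                latitude=float(lat.iloc[i]),
                longitude=float(lon.iloc[i]),
                month=None if pd.isna(months.iloc[i]) else int(months.iloc[i]),
                year=None if pd.isna(years.iloc[i]) else int(years.iloc[i]),
                source=source,
            )
        )
    log = pd.DataFrame(rejected, columns=["row", "reason"])
    logger.info("read %d rows from %s: %d accepted, %d rejected",
                len(df), path, len(accepted), len(log))
    return accepted, log


def filter_taxonomy(
    reports: Iterable[Report], whitelist: GenusWhitelist | None = None
) -> list[Report]:
    """Keep reports whose genus is whitelisted; normalize label spelling.

    Matching is case-insensitive; retained reports carry the canonical
    whitelist spelling, which makes the operation idempotent.
    """
    wl = whitelist or GenusWhitelist()
    kept: list[Report] = []
    removed = 0
    for r in reports:
        canon = wl.normalize(r.genus)
        if canon is None:
            removed += 1
            continue
        kept.append(r if r.genus == canon else dataclasses.replace(r, genus=canon))
    logger.info("taxonomy filter: kept %d reports, removed %d", len(kept), removed)
    return kept
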