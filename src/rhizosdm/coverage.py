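"""Sample-coverage screening of occurrence data.

Raw reports are aggregated to a per-genus abundance vector — the number
of reports at each distinct rounded coordinate — and the abundance-based
sample-coverage estimator of Chao & Jost (the estimator behind iNEXT's
rarefaction curves) is evaluated at the observed sample size.  Genera
whose estimated coverage exceeds the threshold (default 0.95, strict
inequality) are considered saturated and retained for modelling.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .ingest import Report


@dataclasses.dataclass
class AbundanceVector:
    """Per-coordinate report counts for one genus (order: lat, then lon)."""

    genus: str
    counts: np.ndarray
    coords: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) and (self.counts < 1).any():
            raise ValueError("abundance counts must be >= 1")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class CoverageResult:
    genus: str
    n: int
    n_coords: int
    sc: float
    retained: bool


def abundance_from_reports(reports: Iterable[Report], genus: str) -> AbundanceVector:
    """Count reports of ``genus`` per distinct (rounded) coordinate.

    Reports are expected to carry coordinates already rounded to the
    aggregation precision (tenths of a degree by default upstream).
    A genus with zero reports yields an empty vector.
    """
    tally: dict[tuple[float, float], int] = {}
    for r in reports:
        if r.genus != genus:
            continue
        key = (r.latitude, r.longitude)
        tally[key] = tally.get(key, 0) + 1
    coords = tuple(sorted(tally))
    counts = np.array([tally[c] for c in coords], dtype=int)
    return AbundanceVector(genus=genus, counts=counts, coords=coords)


def sample_coverage(av: AbundanceVector | Sequence[int]) -> float:
    """Abundance-based sample-coverage estimate in [0, 1].

    Chao–Jost estimator: ``C = 1 - (f1/n) * [(n-1)f1 / ((n-1)f1 + 2 f2)]``
    with n the total count, f1/f2 the number of coordinates seen exactly
    once/twice.  When ``f2 == 0`` (and ``f1 > 0``) the bias-corrected
    iNEXT form substitutes ``(n-1)(f1-1) / ((n-1)(f1-1) + 2)``.

    Conventions: coverage is exactly 1 when there are no singletons; a
    sample consisting of a single report (n == 1) is treated as carrying
    no coverage information and returns 0.0.
    """
    counts = av.counts if isinstance(av, AbundanceVector) else np.asarray(av, dtype=int)
    if len(counts) == 0:
        raise ValueError("no reports")
    if (counts < 1).any():
        raise ValueError("abundance counts must be >= 1")
    n = int(counts.sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    if f2 > 0:
        a = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    else:
        a = (n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2)
    return float(1.0 - (f1 / n) * a)


def retain_genera(
    reports: Iterable[Report],
    threshold: float = 0.95,
    genera: Sequence[str] | None = None,
) -> list[CoverageResult]:
    """Coverage-screen every genus; retained iff ``sc > threshold`` (strict).

    ``reports`` must already be coordinate-rounded.  ``genera`` fixes the
    evaluation order (default: order of first appearance).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    reports = list(reports)
    if genera is None:
        seen: list[str] = []
        for r in reports:
            if r.genus not in seen:
                seen.append(r.genus)
        genera = seen
    results = []
    for g in genera:
        av = abundance_from_reports(reports, g)
        if av.n == 0:
            results.append(CoverageResult(g, 0, 0, 0.0, False))
            continue
        sc = sample_coverage(av)
        results.append(
            CoverageResult(
                genus=g,
                n=av.n,
                n_coords=len(av.counts),
                sc=sc,
                retained=sc > threshold,
            )
        )
    return results
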