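"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from rhizosdm import synth
from rhizosdm.envpair import CuratedFrame
from rhizosdm.fields import DEPTHS, PREDICTORS, VARIABLES, build_dataset, grid_centers


@pytest.fixture(scope="session")
def tiny_env():
    """Small (18 x 36) synthetic climatology shared across tests."""
    return synth.make_environment(seed=7, lat_step=10.0, months=12,
                                  land_fraction=0.25)


@pytest.fixture(scope="session")
def tiny_env_uniform_effort(tiny_env):
    return synth.ParticipationSurface.uniform(tiny_env)


def make_flat_env(value: float = 10.0, resolution: float = 10.0,
                  months: int = 12, land: np.ndarray | None = None):
    """A climatology with every field constant (NaN where ``land`` is True)."""
    lats = grid_centers(-90.0, 90.0, resolution)
    lons = grid_centers(-180.0, 180.0, resolution)
    shape = (months, len(DEPTHS), len(lats), len(lons))
    cubes = {}
    for v in VARIABLES:
        cube = np.full(shape, float(value))
        if land is not None:
            cube[:, :, land] = np.nan
        cubes[v] = cube
    return build_dataset(cubes, lats, lons, range(1, months + 1), resolution)


@pytest.fixture
def flat_env():
    return make_flat_env


def make_synthetic_frame(n_rows: int, genera: tuple[str, ...], seed: int,
                         driver: str | None = None, effect: float = 2.0,
                         base_p: float = 0.3) -> CuratedFrame:
    """A curated frame with iid standard-normal predictors.

    When ``driver`` is set, the first genus' presence probability follows
    a Gaussian suitability kernel on that predictor; all other structure
    is noise.  Rows with no positive genus are resampled away to satisfy
    the frame invariant.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, len(PREDICTORS)))
    counts = np.zeros((n_rows, len(genera)), dtype=int)
    for gi, g in enumerate(genera):
        if driver is not None and gi == 0:
            z = X[:, PREDICTORS.index(driver)]
            p = 0.9 * np.exp(-0.5 * (z / (1.0 / effect)) ** 2)
        else:
            p = np.full(n_rows, base_p)
        counts[:, gi] = rng.poisson(2.0 * p) + (rng.random(n_rows) < p)
    empty = counts.sum(axis=1) == 0
    counts[empty, rng.integers(0, len(genera), int(empty.sum()))] += 1
    df = pd.DataFrame(X, columns=list(PREDICTORS))
    for gi, g in enumerate(genera):
        df.insert(gi, g, counts[:, gi])
    df.insert(0, "month", rng.integers(1, 13, n_rows))
    df.insert(0, "lon", rng.uniform(-180, 180, n_rows))
    df.insert(0, "lat", rng.uniform(-90, 90, n_rows))
    return CuratedFrame(df=df, genera=tuple(genera), map_step=2.0, window=2.0)


@pytest.fixture
def synthetic_frame():
    return make_synthetic_frame


# ---------------------------------------------------------------------------
# Independent oracles (plain-python recomputations, no package code)
# ---------------------------------------------------------------------------


def coverage_oracle(counts) -> float:
    """Chao–Jost abundance-based coverage, written out longhand."""
    counts = list(counts)
    n = sum(counts)
    tally = Counter(counts)
    f1, f2 = tally.get(1, 0), tally.get(2, 0)
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    if f2 > 0:
        adj = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    else:
        adj = (n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2)
    return 1.0 - f1 / n * adj


def gap_selection_oracle(importance: dict[str, float],
                         canonical=PREDICTORS) -> tuple[str, ...]:
    """Enumerate every cut point; argmax gap with the extension rule."""
    canon = {p: i for i, p in enumerate(canonical)}
    ordered = sorted(importance,
                     key=lambda p: (-importance[p], canon.get(p, len(canon)), p))
    vals = [importance[p] for p in ordered]
    cuts = list(range(1, len(vals)))        # cut after position k keeps k
    gaps = {k: vals[k - 1] - vals[k] for k in cuts}
    best_gap = max(gaps.values())
    keep = min(k for k in cuts if gaps[k] == best_gap)
    if keep == 1 and len(cuts) > 1:
        rest = {k: g for k, g in gaps.items() if k != 1}
        second_gap = max(rest.values())
        keep = min(k for k in rest if rest[k] == second_gap)
    return tuple(ordered[:keep])
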