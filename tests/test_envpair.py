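"""Report-climatology pairing and curated-frame assembly."""

import numpy as np
import pytest

from conftest import make_flat_env
from rhizosdm import envpair
from rhizosdm.fields import PREDICTORS, VARIABLES, DEPTHS, build_dataset, grid_centers
from rhizosdm.ingest import Report


def _rep(lat, lon, month=1, genus="Cassiopea", rid=None):
    return Report(rid or f"{genus}-{lat}-{lon}-{month}", genus, lat, lon, month)


def _env_with_values(values_2d, resolution=10.0, months=1):
    """Flat env whose every (var, depth, month) slice equals ``values_2d``."""
    values_2d = np.asarray(values_2d, dtype=float)
    lats = grid_centers(-90, 90, resolution)
    lons = grid_centers(-180, 180, resolution)
    cube = np.broadcast_to(values_2d, (months, len(DEPTHS), *values_2d.shape)).copy()
    return build_dataset({v: cube.copy() for v in VARIABLES}, lats, lons,
                         range(1, months + 1), resolution)


class TestPairReport:
    def test_uniform_field_gives_the_value(self):
        env = make_flat_env(value=10.0, resolution=10.0)
        prof = envpair.pair_report(_rep(0.0, 0.0), env, window=10.0)
        assert not prof.unpairable
        assert all(v == pytest.approx(10.0) for v in prof.values.values())

    def test_mean_of_two_matching_cells(self):
        vals = np.full((18, 36), np.nan)
        vals[9, 18] = 10.0   # lat 5, lon 5
        vals[9, 17] = 20.0   # lat 5, lon -5
        env = _env_with_values(vals)
        prof = envpair.pair_report(_rep(5.0, 0.0), env, window=10.0)
        assert prof.values["temperature_0m"] == pytest.approx(15.0)
        assert prof.n_cells["temperature_0m"] == 2

    def test_longitude_window_wraps_the_dateline(self):
        env = make_flat_env(value=1.0, resolution=10.0)
        report = _rep(0.0, 179.5)
        # brute-force membership: every cell center within the wrapped box
        expected = 0
        for lon in env.lons:
            d = abs((lon - 179.5 + 180.0) % 360.0 - 180.0)
            if d <= 10.0:
                expected += 1
        prof = envpair.pair_report(report, env, window=10.0)
        n_lat = int((np.abs(env.lats - 0.0) <= 10.0).sum())
        assert prof.n_cells["temperature_0m"] == expected * n_lat
        assert -175.0 in env.lons[np.abs((env.lons - 179.5 + 180) % 360 - 180) <= 10]

    def test_all_land_window_is_unpairable(self):
        land = np.ones((18, 36), dtype=bool)
        land[0, 0] = False  # one far-away ocean cell keeps the env valid
        env = make_flat_env(value=5.0, resolution=10.0, land=land)
        prof = envpair.pair_report(_rep(0.0, 0.0), env, window=10.0)
        assert prof.unpairable

    def test_missing_month_is_an_error(self):
        env = make_flat_env(resolution=10.0, months=3)
        with pytest.raises(ValueError, match="month"):
            envpair.pair_report(_rep(0.0, 0.0, month=9), env, window=10.0)

    def test_widening_window_never_loses_cells(self):
        env = make_flat_env(value=2.0, resolution=10.0)
        r = _rep(13.0, 47.0)
        narrow = envpair.pair_report(r, env, window=5.0)
        wide = envpair.pair_report(r, env, window=25.0)
        for pid in PREDICTORS:
            assert wide.n_cells[pid] >= narrow.n_cells[pid]


class TestBuildFrame:
    def test_counts_accumulate_per_cell(self):
        env = make_flat_env(value=1.0, resolution=2.0)
        reports = [_rep(10.1, 20.1, rid="a"), _rep(10.3, 20.3, rid="b"),
                   _rep(50.0, -60.0, rid="c")]
        frame = envpair.build_frame(reports, env, map_step=2.0, window=2.0)
        assert len(frame.df) == 2
        assert sorted(frame.df["Cassiopea"]) == [1, 2]

    def test_count_conservation_over_rows(self, tiny_env):
        from rhizosdm import synth
        reports = synth.sample_reports(
            synth.default_niches()[:3], tiny_env,
            synth.ParticipationSurface.uniform(tiny_env), 60, seed=5)
        frame = envpair.build_frame(reports, tiny_env, map_step=10.0, window=10.0)
        for g in frame.genera:
            n_pairable = sum(1 for r in reports if r.genus == g) - sum(
                1 for r in reports if r.genus == g and
                envpair.pair_report(r, tiny_env, 10.0).unpairable)
            assert frame.df[g].sum() == n_pairable

    def test_finer_mapping_has_at_least_as_many_rows(self, tiny_env):
        from rhizosdm import synth
        reports = synth.sample_reports(
            synth.default_niches()[:3], tiny_env,
            synth.ParticipationSurface.uniform(tiny_env), 80, seed=6)
        f1 = envpair.build_frame(reports, tiny_env, map_step=1.0, window=10.0)
        f2 = envpair.build_frame(reports, tiny_env, map_step=2.0, window=10.0)
        assert len(f1.df) >= len(f2.df)

    def test_row_profile_is_mean_of_member_profiles(self, tiny_env):
        from rhizosdm import synth
        reports = synth.sample_reports(
            synth.default_niches()[:2], tiny_env,
            synth.ParticipationSurface.uniform(tiny_env), 50, seed=7)
        frame = envpair.build_frame(reports, tiny_env, map_step=10.0, window=10.0)
        # brute-force oracle: recompute each row's profile from scratch
        for _, row in frame.df.head(10).iterrows():
            members = [r for r in reports
                       if envpair.snap_to_cell(r.latitude, r.longitude, 10.0)
                       == (row["lat"], row["lon"]) and r.month == row["month"]]
            assert members
            stack = np.vstack([envpair.pair_report(r, tiny_env, 10.0).as_array()
                               for r in members])
            with np.errstate(invalid="ignore"):
                expected = np.nanmean(stack, axis=0)
            np.testing.assert_allclose(
                row[list(PREDICTORS)].to_numpy(dtype=float), expected)

    def test_translation_consistency_in_longitude(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(18, 36))
        env = _env_with_values(vals)
        shifted = _env_with_values(np.roll(vals, 1, axis=1))  # +10 deg lon
        r = _rep(5.0, 15.0)
        r_shift = _rep(5.0, 25.0)
        a = envpair.pair_report(r, env, window=10.0)
        b = envpair.pair_report(r_shift, shifted, window=10.0)
        assert a.values["salinity_5m"] == pytest.approx(b.values["salinity_5m"])

    def test_empty_reports_empty_frame(self, tiny_env):
        frame = envpair.build_frame([], tiny_env)
        assert len(frame.df) == 0

    def test_frame_csv_roundtrip(self, tmp_path, tiny_env):
        from rhizosdm import synth
        reports = synth.sample_reports(
            synth.default_niches()[:3], tiny_env,
            synth.ParticipationSurface.uniform(tiny_env), 40, seed=8)
        frame = envpair.build_frame(reports, tiny_env, map_step=10.0, window=10.0)
        path = tmp_path / "frame.csv"
        frame.df.to_csv(path, index=False)
        back = envpair.frame_from_csv(path, map_step=10.0, window=10.0)
        assert back.genera == frame.genera
        np.testing.assert_allclose(back.profiles().to_numpy(),
                                   frame.profiles().to_numpy())


class TestImputation:
    def test_median_imputation_with_audit(self, synthetic_frame):
        frame = synthetic_frame(30, ("A", "B"), seed=1)
        frame.df.loc[3, "temperature_0m"] = np.nan
        X, audit = envpair.impute_for_model(frame)
        med = frame.df["temperature_0m"].median()
        assert X.loc[3, "temperature_0m"] == pytest.approx(med)
        assert audit.loc[3, "temperature_0m"] and audit.to_numpy().sum() == 1
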