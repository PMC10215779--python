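"""Synthetic climatology and report generator behaviour."""

import numpy as np
import pytest

from rhizosdm import synth
from rhizosdm.envpair import build_frame, pair_report
from rhizosdm.envelope import build_envelope
from rhizosdm.fields import DEPTHS, PREDICTORS, VARIABLES


def _niche(pid="temperature_20m", mean=25.0, sd=1.0, genus="Testus"):
    return synth.NicheSpec(genus=genus, optima={pid: (mean, sd)},
                           informative_set=(pid,))


class TestMakeEnvironment:
    def test_grid_shape_follows_lat_step(self):
        env = synth.make_environment(seed=1, lat_step=2.0, months=2)
        assert env.predictor_grid("temperature_0m", 1).shape == (90, 180)
        assert list(env.months) == [1, 2]

    def test_same_seed_is_bit_identical(self):
        a = synth.make_environment(seed=3, lat_step=10.0, months=3)
        b = synth.make_environment(seed=3, lat_step=10.0, months=3)
        for v in VARIABLES:
            np.testing.assert_array_equal(a.ds[v].values, b.ds[v].values)

    def test_land_mask_shared_and_fractional(self, tiny_env):
        mask = tiny_env.ocean_mask
        assert 0.70 < mask.mean() < 0.80  # requested 25% land
        for v in VARIABLES:
            finite = np.isfinite(tiny_env.ds[v].values)
            assert (finite == mask[None, None]).all()

    def test_fields_vary_across_depth_and_month(self, tiny_env):
        t = tiny_env.ds["temperature"]
        assert not np.allclose(t.sel(depth=0).values, t.sel(depth=20).values,
                               equal_nan=True)
        assert not np.allclose(t.sel(month=1).values, t.sel(month=7).values,
                               equal_nan=True)

    @pytest.mark.parametrize("bad", [7.0, 0.0, -2.0])
    def test_invalid_lat_step_rejected(self, bad):
        with pytest.raises(ValueError, match="lat_step"):
            synth.make_environment(seed=1, lat_step=bad)

    def test_invalid_months_rejected(self):
        with pytest.raises(ValueError, match="months"):
            synth.make_environment(seed=1, lat_step=10.0, months=0)


class TestSampleReports:
    def test_determinism(self, tiny_env, tiny_env_uniform_effort):
        niches = [_niche()]
        a = synth.sample_reports(niches, tiny_env, tiny_env_uniform_effort, 100, seed=5)
        b = synth.sample_reports(niches, tiny_env, tiny_env_uniform_effort, 100, seed=5)
        assert a == b

    def test_reports_never_on_land(self, tiny_env, tiny_env_uniform_effort):
        reports = synth.sample_reports([_niche()], tiny_env,
                                       tiny_env_uniform_effort, 300, seed=2)
        ocean = tiny_env.ocean_mask
        for r in reports:
            i, j = tiny_env.cell_index(r.latitude, r.longitude)
            assert ocean[i, j]

    def test_zero_effort_yields_zero_reports(self, tiny_env):
        effort = synth.ParticipationSurface.uniform(tiny_env)
        effort.weight[:] = 0.0  # zeroed post-validation: the op must cope
        out = synth.sample_reports(synth.default_niches(), tiny_env, effort,
                                   200, seed=1)
        assert out == []

    @pytest.mark.parametrize("clustering", ["sites", "none"])
    def test_reports_track_the_informative_predictor(
            self, tiny_env, tiny_env_uniform_effort, clustering):
        # Gaussian kernel, mean 25 sd 1 -> ~95% of the sampling mass lies
        # within +/-2 sd; count it on the realized sample
        niche = _niche("temperature_20m", 25.0, 1.0)
        reports = synth.sample_reports([niche], tiny_env, tiny_env_uniform_effort,
                                       400, seed=9, clustering=clustering)
        assert len(reports) > 200
        cube = tiny_env.predictor_cube("temperature_20m")
        month_ix = {int(m): k for k, m in enumerate(tiny_env.months)}
        hits = 0
        for r in reports:
            i, j = tiny_env.cell_index(r.latitude, r.longitude)
            hits += abs(cube[month_ix[r.month], i, j] - 25.0) <= 2.0
        assert hits / len(reports) >= 0.90

    def test_base_rate_monotone_in_expectation(self, tiny_env, tiny_env_uniform_effort):
        lo = hi = 0
        for seed in range(6):
            for rate, bump in ((0.02, "lo"), (0.2, "hi")):
                n = synth.NicheSpec(genus="T", optima={"temperature_0m": (25.0, 2.0)},
                                    informative_set=("temperature_0m",),
                                    base_rate=rate)
                cnt = len(synth.sample_reports([n], tiny_env, tiny_env_uniform_effort,
                                               None, seed=seed))
                if bump == "lo":
                    lo += cnt
                else:
                    hi += cnt
        assert hi > lo

    def test_impossible_niche_flagged_empty(self, tiny_env, tiny_env_uniform_effort, caplog):
        bad = synth.NicheSpec(genus="Ghost",
                              optima={"temperature_0m": (400.0, 0.1)},
                              informative_set=("temperature_0m",))
        with caplog.at_level("WARNING"):
            out = synth.sample_reports([bad], tiny_env, tiny_env_uniform_effort,
                                       50, seed=1)
        assert out == []
        assert any("zero total intensity" in m for m in caplog.messages)

    def test_niche_spec_validation(self):
        with pytest.raises(ValueError, match="informative_set"):
            synth.NicheSpec("X", {"temperature_0m": (20.0, 1.0)}, ())
        with pytest.raises(ValueError, match="sd"):
            synth.NicheSpec("X", {"temperature_0m": (20.0, 0.0)},
                            ("temperature_0m",))
        with pytest.raises(ValueError, match="unknown predictor"):
            synth.NicheSpec("X", {"bathymetry_0m": (20.0, 1.0)}, ("bathymetry_0m",))


class TestSampleLegacy:
    def test_zero_n_empty_and_source_tag(self, tiny_env):
        assert synth.sample_legacy([_niche()], tiny_env, 0, seed=1) == []
        out = synth.sample_legacy([_niche()], tiny_env, 30, seed=1)
        assert out and all(r.source == "legacy" for r in out)

    def test_legacy_falls_inside_envelope_from_abundant_reports(
            self, tiny_env, tiny_env_uniform_effort):
        # envelope built per predictor at the central 90%: two independent
        # selected predictors give joint containment >= 0.9^2 = 0.81 in
        # expectation for fresh draws from the same niche
        pids = ("temperature_10m", "salinity_0m")
        niche = synth.NicheSpec(
            genus="Testus",
            optima={pids[0]: (24.0, 2.0), pids[1]: (34.8, 0.8)},
            informative_set=pids,
        )
        reports = synth.sample_reports([niche], tiny_env, tiny_env_uniform_effort,
                                       800, seed=3)
        # the pairing window is scaled to the coarse 10-degree test grid
        frame = build_frame(reports, tiny_env, map_step=10.0, window=10.0)
        positives = frame.df[frame.df["Testus"] > 0]
        env_box = build_envelope(positives[list(PREDICTORS)], pids, 0.90)
        legacy = synth.sample_legacy([niche], tiny_env, 500, seed=4)
        inside = 0
        for r in legacy:
            prof = pair_report(r, tiny_env, window=10.0).values
            inside += all(env_box.bounds[p][0] <= prof[p] <= env_box.bounds[p][1]
                          for p in pids)
        assert inside / len(legacy) >= 0.78  # 0.81 minus Monte-Carlo slack


class TestParticipationSurface:
    def test_weight_bounds_enforced(self, tiny_env):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            synth.ParticipationSurface(np.full((3, 3), 1.5))
        with pytest.raises(ValueError, match="positive"):
            synth.ParticipationSurface(np.zeros((3, 3)))

    def test_western_bias_is_heterogeneous(self, tiny_env):
        eff = synth.ParticipationSurface.western_bias(tiny_env)
        assert eff.weight.max() > 5 * eff.weight.min()
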