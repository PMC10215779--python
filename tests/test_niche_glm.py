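"""Negative-binomial GLM, multivariate permutation test, biplot, Dunn letters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_synthetic_frame
from rhizosdm import niche_glm


def _nb_draws(rng, mu, alpha):
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))


class TestFitNbGlm:
    def test_intercept_only_recovers_log_mean(self):
        y = np.full(50, 5.0)
        fit = niche_glm.fit_nb_glm(y, np.ones((50, 1)))
        assert fit.coef[0] == pytest.approx(np.log(5.0), abs=1e-6)

    def test_slope_recovery_on_simulated_counts(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.standard_normal(n)
        mu = np.exp(0.3 + 0.5 * x)
        y = _nb_draws(rng, mu, 0.5).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = niche_glm.fit_nb_glm(y, X)
        assert fit.coef[1] == pytest.approx(0.5, abs=0.1)
        assert 0.2 < fit.alpha < 1.0

    def test_negative_counts_hard_error(self):
        with pytest.raises(ValueError, match="negative count"):
            niche_glm.fit_nb_glm([1, -1, 2], np.ones((3, 1)))

    def test_all_zero_counts_flagged_degenerate(self):
        fit = niche_glm.fit_nb_glm(np.zeros(20), np.ones((20, 1)))
        assert fit.degenerate and fit.coef[0] <= -20

    def test_fast_irls_matches_statsmodels_fit(self):
        # dual route: the permutation-loop solver must agree with the
        # statsmodels IRLS at the same fixed dispersion
        rng = np.random.default_rng(7)
        n = 300
        x = rng.standard_normal(n)
        y = _nb_draws(rng, np.exp(0.5 + 0.8 * x), 0.4).astype(float)
        X = np.column_stack([np.ones(n), x])
        ref = niche_glm.fit_nb_glm(y, X)
        beta, llf, converged = niche_glm.nb_irls(y, X, ref.alpha)
        assert converged
        np.testing.assert_allclose(beta, ref.coef, rtol=1e-4, atol=1e-5)
        assert llf == pytest.approx(ref.llf, abs=1e-4)


class TestManyglm:
    def test_identical_counts_zero_statistic(self, synthetic_frame):
        frame = synthetic_frame(40, ("A", "B"), seed=3)
        frame.df[["A", "B"]] = 3  # same count on every row
        res = niche_glm.manyglm_test(frame, predictors=["temperature_0m",
                                                        "salinity_0m"],
                                     n_resamples=99, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == 1.0

    def test_strong_effect_reaches_minimal_p(self):
        rng = np.random.default_rng(11)
        n = 120
        z = rng.standard_normal(n)
        frame = make_synthetic_frame(n, ("A", "B"), seed=12)
        frame.df["temperature_0m"] = z
        frame.df["A"] = np.round(np.exp(1.5 * z)).astype(int)
        frame.df["B"] = np.round(np.exp(-1.2 * z)).astype(int)
        frame.df.loc[(frame.df["A"] + frame.df["B"]) == 0, "A"] = 1
        res = niche_glm.manyglm_test(frame, predictors=["temperature_0m"],
                                     n_resamples=99, seed=5)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_statistic_invariant_to_genus_order(self, synthetic_frame):
        frame = synthetic_frame(60, ("A", "B", "C"), seed=9,
                                driver="salinity_0m")
        res1 = niche_glm.manyglm_test(frame, predictors=["salinity_0m"],
                                      n_resamples=49, seed=2)
        cols = list(frame.df.columns)
        for a, b in (("A", "C"),):
            i, j = cols.index(a), cols.index(b)
            cols[i], cols[j] = cols[j], cols[i]
        import dataclasses
        frame2 = dataclasses.replace(frame, df=frame.df[cols],
                                     genera=("C", "B", "A"))
        res2 = niche_glm.manyglm_test(frame2, predictors=["salinity_0m"],
                                      n_resamples=49, seed=2)
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-8)

    def test_single_genus_rejected(self, synthetic_frame):
        frame = synthetic_frame(30, ("A",), seed=1)
        with pytest.raises(ValueError, match="two genera"):
            niche_glm.manyglm_test(frame)

    def test_low_resample_warning_recorded(self, synthetic_frame):
        frame = synthetic_frame(30, ("A", "B"), seed=1)
        res = niche_glm.manyglm_test(frame, predictors=["nitrate_0m"],
                                     n_resamples=19, seed=1)
        assert any("low" in w for w in res.warnings)


class TestBiplot:
    @pytest.fixture
    def coefs(self):
        rng = np.random.default_rng(5)
        return pd.DataFrame(rng.normal(size=(5, 6)),
                            index=list("ABCDE"),
                            columns=[f"p{i}" for i in range(6)])

    def test_identical_rows_identical_coordinates(self, coefs):
        coefs.loc["B"] = coefs.loc["A"]
        scores, _, _ = niche_glm.niche_biplot(coefs)
        np.testing.assert_allclose(scores.loc["A"], scores.loc["B"], atol=1e-10)

    def test_invariant_to_predictor_column_order(self, coefs):
        s1, _, _ = niche_glm.niche_biplot(coefs)
        s2, _, _ = niche_glm.niche_biplot(coefs[coefs.columns[::-1]])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)

    def test_explained_variance_non_increasing(self, coefs):
        _, explained, _ = niche_glm.niche_biplot(coefs)
        assert explained[0] >= explained[1] >= 0

    def test_fewer_than_three_genera_error(self, coefs):
        with pytest.raises(ValueError, match="3 genera"):
            niche_glm.niche_biplot(coefs.iloc[:2])

    def test_perturbation_grows_biplot_distance_monotonically(self):
        # enough genera that one perturbed entry barely moves the column
        # standardization; distance then tracks the perturbation size
        rng = np.random.default_rng(5)
        coefs = pd.DataFrame(rng.normal(size=(12, 6)),
                             index=[f"G{i}" for i in range(12)],
                             columns=[f"p{i}" for i in range(6)])
        dists = []
        for eps in (0.05, 0.1, 0.2, 0.4, 0.8):
            c = coefs.copy()
            c.loc["G11"] = c.loc["G0"]
            c.loc["G11", "p0"] += eps
            scores, _, _ = niche_glm.niche_biplot(c)
            dists.append(float(np.linalg.norm(scores.loc["G0"] - scores.loc["G11"])))
        assert dists == sorted(dists)
        assert dists[0] > 0


class TestKruskalDunn:
    def test_identical_groups_share_a_letter(self):
        vals = list(range(30))
        res = niche_glm.kruskal_dunn_letters({"A": vals, "B": vals})
        assert set(res.letters["A"]) & set(res.letters["B"])

    def test_separated_groups_get_distinct_letters(self):
        a = np.arange(50, dtype=float)
        b = a + 1000.0
        res = niche_glm.kruskal_dunn_letters({"A": a, "B": b})
        assert not (set(res.letters["A"]) & set(res.letters["B"]))
        # direct z computation for the two-group no-tie case
        n = 50
        N = 2 * n
        se = np.sqrt((N * (N + 1) / 12.0) * (2.0 / n))
        z = (np.mean(stats.rankdata(np.concatenate([a, b]))[:n])
             - np.mean(stats.rankdata(np.concatenate([a, b]))[n:])) / se
        assert res.pairwise_p.loc["A", "B"] == pytest.approx(
            2 * stats.norm.sf(abs(z)))
        assert res.pairwise_p.loc["A", "B"] < 0.05

    def test_overlap_chain_yields_shared_middle_letters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.4, 1.0, 20)
        c = rng.normal(0.8, 1.0, 20)
        res = niche_glm.kruskal_dunn_letters({"A": a, "B": b, "C": c})
        P = res.pairwise_p
        assert P.loc["A", "B"] >= 0.05 and P.loc["B", "C"] >= 0.05
        assert P.loc["A", "C"] < 0.05
        assert res.letters["B"] == "ab"
        assert res.letters["A"] != res.letters["C"]

    def test_letters_mirror_nonsignificance_graph_exactly(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(loc, 1.0, 40)
                  for g, loc in zip("ABCDEF", [0, 0.4, 0.8, 1.6, 3.0, 3.2])}
        res = niche_glm.kruskal_dunn_letters(groups)
        for gi in groups:
            for gj in groups:
                if gi == gj:
                    continue
                share = bool(set(res.letters[gi]) & set(res.letters[gj]))
                nonsig = res.pairwise_p.loc[gi, gj] >= res.alpha
                assert share == nonsig, (gi, gj)

    def test_single_group_error(self):
        with pytest.raises(ValueError, match="two groups"):
            niche_glm.kruskal_dunn_letters({"A": [1, 2, 3]})

    def test_kw_statistic_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(i, 1, 30) for i, g in enumerate("ABC")}
        res = niche_glm.kruskal_dunn_letters(groups)
        ref_stat, ref_p = stats.kruskal(*groups.values())
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    def test_holm_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(4)
        groups = {g: rng.normal(i * 0.5, 1, 40) for i, g in enumerate("ABCD")}
        plain = niche_glm.kruskal_dunn_letters(groups, adjust="none")
        holm = niche_glm.kruskal_dunn_letters(groups, adjust="holm")
        assert (holm.pairwise_p.to_numpy() >= plain.pairwise_p.to_numpy() - 1e-12).all()
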