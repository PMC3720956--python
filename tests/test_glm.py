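"""GLM calibration tests: closed forms, family choice, parameter
recovery, stepwise selection behaviour and fit statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from stageniche.glm import (FamilySpec, category_deviance, choose_family,
                            fit_glm, nagelkerke_r2, stepwise_aic)

BIN = FamilySpec("binomial")


def nb_table(rng, n, k, beta0=0.5, beta1=0.8):
    x = rng.standard_normal(n)
    mean = np.exp(beta0 + beta1 * x)
    lam = rng.gamma(k, mean / k)
    return pd.DataFrame({"x": x, "y": rng.poisson(lam)})


class TestFitGlm:
    def test_intercept_only_binomial_closed_form(self):
        # intercept = logit(30/100)
        df = pd.DataFrame({"y": [1] * 30 + [0] * 70})
        m = fit_glm(df, "y", [], BIN)
        assert m.params["const"] == pytest.approx(logit(0.3), abs=1e-6)

    def test_null_model_residual_equals_null_deviance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.binomial(1, 0.4, 100)})
        m = fit_glm(df, "y", [], BIN)
        assert m.deviance == pytest.approx(m.null_deviance, abs=1e-8)

    def test_logistic_coefficient_ci_coverage(self):
        # generating coefficients fall inside their 95% Wald CIs at the
        # nominal rate (>= 90/100 seeded replicates)
        rng = np.random.default_rng(1)
        beta = np.array([0.8, -0.5])
        cover = {"a": 0, "b": 0}
        for _ in range(100):
            X = rng.standard_normal((2000, 2))
            y = rng.binomial(1, expit(-0.3 + X @ beta))
            df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "y": y})
            m = fit_glm(df, "y", ["a", "b"], BIN)
            for nm, b in zip(("a", "b"), beta):
                cover[nm] += abs(m.params[nm] - b) <= 1.96 * m.bse[nm]
        assert min(cover.values()) >= 90

    def test_separation_flagged_with_bounded_fallback(self):
        x = np.linspace(-2, 2, 60)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(int)})
        m = fit_glm(df, "y", ["x"], BIN)
        assert m.separation
        assert np.isfinite(m.params["x"])
        assert m.explained_deviance > 0.95

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(50), "y": np.tile([0, 1], 25)})
        with pytest.raises(ValueError, match="constant"):
            fit_glm(df, "y", ["x"], BIN)

    def test_nb_poisson_agreement_on_equidispersed_counts(self):
        # with no aggregation the NB fit collapses onto the Poisson fit
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        df = pd.DataFrame({"x": x, "y": rng.poisson(np.exp(0.5 + 0.6 * x))})
        mp = fit_glm(df, "y", ["x"], FamilySpec("poisson"))
        mnb = fit_glm(df, "y", ["x"], FamilySpec("negative_binomial"))
        np.testing.assert_allclose(mnb.params, mp.params, atol=1e-3)


class TestChooseFamily:
    def test_binary_pa_keeps_binomial(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.binomial(1, 0.4, 300)})
        assert choose_family(df, "PA", "y").family == "binomial"

    def test_aggregated_counts_choose_nb_and_recover_k(self):
        rng = np.random.default_rng(4)
        df = nb_table(rng, 1000, k=0.5, beta1=0.0)
        spec = choose_family(df, "AB", "y")
        assert spec.family == "negative_binomial"
        assert 0.3 <= spec.k <= 0.8

    def test_poisson_counts_choose_poisson(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.poisson(3.0, 1000)})
        assert choose_family(df, "AB", "y").family == "poisson"

    def test_underdispersed_counts_fall_back_to_poisson(self):
        df = pd.DataFrame({"y": np.tile([2, 2, 2, 3], 50)})
        assert choose_family(df, "AB", "y").family == "poisson"


class TestStepwise:
    def test_noise_predictor_usually_dropped(self):
        # AIC retains a null term only with P(chi2_1 > 2) ~ 0.157
        rng = np.random.default_rng(6)
        kept = 0
        n_rep = 100
        for _ in range(n_rep):
            df = pd.DataFrame({"x": rng.standard_normal(1000),
                               "y": rng.binomial(1, 0.5, 1000)})
            mam = stepwise_aic(df, "y", ["x"], BIN)
            kept += bool(mam.predictors)
        assert kept / n_rep < 0.5  # intercept-only MAM in the majority
        assert 0.03 < kept / n_rep < 0.35  # near the theoretical 0.157

    def test_informative_predictor_retained(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(500)
        df = pd.DataFrame({"x": x, "y": rng.binomial(1, expit(2 * x))})
        mam = stepwise_aic(df, "y", ["x"], BIN)
        assert mam.predictors == ["x"]

    def test_mam_aic_beats_both_start_points(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((300, 4))
        eta = 1.2 * X[:, 0] - 0.8 * X[:, 1]
        df = pd.DataFrame(X, columns=list("abcd"))
        df["y"] = rng.binomial(1, expit(eta))
        scope = list("abcd")
        mam = stepwise_aic(df, "y", scope, BIN)
        full = fit_glm(df, "y", scope, BIN)
        null = fit_glm(df, "y", [], BIN)
        assert mam.aic <= full.aic + 1e-9
        assert mam.aic <= null.aic + 1e-9

    def test_adding_predictors_never_increases_deviance(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((200, 3))
        df = pd.DataFrame(X, columns=list("abc"))
        df["y"] = rng.binomial(1, expit(X[:, 0]))
        subsets = [[], ["a"], ["a", "b"], ["a", "b", "c"]]
        devs = [fit_glm(df, "y", s, BIN).deviance for s in subsets]
        assert all(d2 <= d1 + 1e-8 for d1, d2 in zip(devs, devs[1:]))


class TestFitStatistics:
    def test_nagelkerke_zero_for_null_fit(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"y": rng.binomial(1, 0.3, 200)})
        assert nagelkerke_r2(fit_glm(df, "y", [], BIN)) == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_nagelkerke_approaches_one_for_perfect_fit(self):
        x = np.linspace(-2, 2, 100)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(int)})
        assert nagelkerke_r2(fit_glm(df, "y", ["x"], BIN)) > 0.95

    def test_nagelkerke_matches_direct_formula(self):
        # independent evaluation of the normalized Cox-Snell form
        rng = np.random.default_rng(11)
        x = rng.standard_normal(20)
        df = pd.DataFrame({"x": x,
                           "y": rng.binomial(1, expit(0.8 * x))})
        m = fit_glm(df, "y", ["x"], BIN)
        d0, d1, n = m.null_deviance, m.deviance, m.n
        expected = (1 - np.exp(-(d0 - d1) / n)) / (1 - np.exp(-d0 / n))
        assert nagelkerke_r2(m) == pytest.approx(expected, abs=1e-10)

    def test_aic_definition(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(150)
        df = pd.DataFrame({"x": x, "y": rng.binomial(1, expit(x))})
        m = fit_glm(df, "y", ["x"], BIN)
        assert m.aic == pytest.approx(-2 * m.llf + 2 * 2, abs=1e-9)


class TestCategoryDeviance:
    def test_single_category_mam_gets_all_explained_deviance(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(300) * 10 + 30
        df = pd.DataFrame({"BARESOIL_1": x,
                           "y": rng.binomial(1, expit(0.1 * (x - 30)))})
        m = fit_glm(df, "y", ["BARESOIL_1"], BIN)
        m.response = "y"
        contrib = category_deviance(m, df)
        assert contrib["COVER"] == pytest.approx(
            m.explained_deviance * 100, abs=1e-8)
        assert contrib["SOIL"] == 0.0  # empty category contributes nothing

    def test_contributions_match_submodel_differences(self):
        rng = np.random.default_rng(14)
        n = 400
        cover = rng.standard_normal(n)
        soil = rng.standard_normal(n)
        df = pd.DataFrame({"BARESOIL_1": cover, "SOIL_PH": soil})
        df["y"] = rng.binomial(1, expit(0.8 * cover - 0.6 * soil))
        m = fit_glm(df, "y", ["BARESOIL_1", "SOIL_PH"], BIN)
        contrib = category_deviance(m, df)
        without_cover = fit_glm(df, "y", ["SOIL_PH"], BIN)
        expected = (without_cover.deviance - m.deviance) / m.null_deviance * 100
        assert contrib["COVER"] == pytest.approx(expected, abs=1e-8)
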