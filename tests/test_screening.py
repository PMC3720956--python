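"""Screening chain tests: univariate retention, correlation filter with
scale competition, and the VIF cascade against its closed form."""

import numpy as np
import pandas as pd
import pytest

from stageniche.glm import FamilySpec
from stageniche.screening import (VariableScreen, compute_vifs,
                                  correlation_filter, screen_predictors,
                                  univariate_screen, vif_cascade)

BIN = FamilySpec("binomial")


def screens_for(names):
    return [VariableScreen(name=n, explained_deviance=1.0 - 0.01 * i,
                           included=True) for i, n in enumerate(names)]


class TestUnivariateScreen:
    def test_perfect_predictor_retained_with_full_deviance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(int)})
        out = univariate_screen(df, "y", ["x"], BIN)
        assert out[0].included
        assert out[0].explained_deviance > 0.95  # separation-guarded fit

    def test_null_predictor_retention_rate_matches_threshold(self):
        # under independence P(p < 0.1) = 0.1: type-I retention calibration
        rng = np.random.default_rng(42)
        y = rng.binomial(1, 0.5, 500)
        kept = 0
        n_rep = 500
        for _ in range(n_rep):
            df = pd.DataFrame({"x": rng.standard_normal(500), "y": y})
            out = univariate_screen(df, "y", ["x"], BIN, p_threshold=0.1)
            kept += out[0].included
        assert 0.07 < kept / n_rep < 0.13

    def test_ranked_by_explained_deviance(self):
        rng = np.random.default_rng(3)
        n = 400
        strong = rng.standard_normal(n)
        weak = rng.standard_normal(n)
        eta = 2.0 * strong + 0.5 * weak
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"weak": weak, "strong": strong, "y": y})
        out = univariate_screen(df, "y", ["weak", "strong"], BIN)
        assert [v.name for v in out if v.included][0] == "strong"

    def test_constant_column_excluded_not_fatal(self):
        df = pd.DataFrame({"c": np.ones(50),
                           "y": np.tile([0, 1], 25)})
        out = univariate_screen(df, "y", ["c"], BIN)
        assert not out[0].included
        assert out[0].exclusion_reason == "fit-failed"


class TestCorrelationFilter:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": x})
        out = correlation_filter(screens_for(["a", "b"]), df)
        by = {v.name: v for v in out}
        assert by["a"].included and not by["b"].included
        assert by["b"].exclusion_reason == "correlated-with:a"

    def test_one_scale_per_multiscale_family(self):
        # three scale versions of the same cover variable compete:
        # only the best-ranked survives, correlated or not
        rng = np.random.default_rng(2)
        df = pd.DataFrame({f"BARESOIL_{s}": rng.standard_normal(100)
                           for s in ("25", "50", "1")})
        out = correlation_filter(
            screens_for(["BARESOIL_50", "BARESOIL_25", "BARESOIL_1"]), df)
        kept = [v.name for v in out if v.included]
        assert kept == ["BARESOIL_50"]
        reasons = {v.name: v.exclusion_reason for v in out if not v.included}
        assert set(reasons.values()) == {"scale-competition"}

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((1000, 3)),
                          columns=["p1", "p2", "p3"])
        out = correlation_filter(screens_for(["p1", "p2", "p3"]), df)
        assert all(v.included for v in out)


class TestVif:
    def test_orthogonal_predictors_vif_one(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({"a": np.cos(2 * np.pi * t / n),
                           "b": np.sin(2 * np.pi * t / n)})
        vifs = compute_vifs(df, ["a", "b"])
        assert vifs["a"] == pytest.approx(1.0, abs=1e-10)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-10)

    def test_two_predictor_closed_form(self):
        # VIF = 1/(1 - r^2) for a two-predictor design
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.standard_normal(500)
        df = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        vifs = compute_vifs(df, ["x", "y"])
        assert vifs["x"] == pytest.approx(1 / (1 - r ** 2), abs=1e-10)
        assert vifs["y"] == pytest.approx(1 / (1 - r ** 2), abs=1e-10)

    def test_three_predictor_matrix_inverse_oracle(self):
        # VIFs equal the diagonal of the inverse correlation matrix
        rng = np.random.default_rng(6)
        X = rng.standard_normal((300, 3)) @ np.array(
            [[1, 0.4, 0.2], [0, 1, 0.5], [0, 0, 1.0]])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        R = np.corrcoef(X, rowvar=False)
        expected = np.diag(np.linalg.inv(R))
        vifs = compute_vifs(df, ["a", "b", "c"])
        np.testing.assert_allclose([vifs["a"], vifs["b"], vifs["c"]],
                                   expected, atol=1e-10)

    def test_exact_collinearity_removed(self):
        rng = np.random.default_rng(7)
        x1, x2 = rng.standard_normal((2, 100))
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        screens = screens_for(["x1", "x2", "x3"])
        final = vif_cascade(df, screens)
        kept = [v.name for v in screens if v.included]
        assert len(kept) <= 2
        assert all(v < 10 for v in final.values())

    def test_cascade_keeps_correlated_below_threshold(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(500)
        y = 0.7 * x + np.sqrt(0.51) * rng.standard_normal(500)
        df = pd.DataFrame({"x": x, "y": y})
        screens = screens_for(["x", "y"])
        final = vif_cascade(df, screens)
        assert all(v.included for v in screens)
        assert all(1.5 < v < 2.5 for v in final.values())


class TestFullChain:
    def test_column_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 300
        X = rng.standard_normal((n, 4))
        eta = 1.5 * X[:, 0] - 1.0 * X[:, 2]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        names = ["HEIGHT", "SOIL_PH", "LITTER_DEPTH", "SOIL_OM"]
        df = pd.DataFrame(X, columns=names)
        df["y"] = y
        r1 = screen_predictors(df, "y", names, BIN)
        r2 = screen_predictors(df, "y", list(reversed(names)), BIN)
        assert sorted(r1.retained) == sorted(r2.retained)

    def test_final_vifs_below_threshold(self, datasets):
        from stageniche import synthetic
        from stageniche.glm import choose_family
        table = datasets[1]
        fam = choose_family(table, "PA", "adult_PA")
        rep = screen_predictors(table, "adult_PA",
                                synthetic.abiotic_columns(1), fam)
        assert all(v < 10 for v in rep.final_vifs.values())
        assert rep.retained  # something survives on informative data

    def test_blocklist_respected(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"HEIGHT": rng.standard_normal(100)})
        df["y"] = rng.binomial(1, 0.5, 100)
        rep = screen_predictors(df, "y", ["HEIGHT"], BIN,
                                blocklist=["HEIGHT"])
        assert "HEIGHT" not in rep.retained
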