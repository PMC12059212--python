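import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nestprospect.glmm import (FitResult, ModelSpec, Term, fit_glm, fit_glmm,
                               fit_hurdle, fit_lmm, odds_ratio, wald_type3,
                               ztpois_logpmf)


def _poisson_glmm_data(G=50, m=10, b0=1.0, b1=0.3, sigma=0.5, seed=42):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(G), m)
    x = rng.normal(size=G * m)
    b = rng.normal(0, sigma, G)
    y = rng.poisson(np.exp(b0 + b1 * x + b[g]))
    return pd.DataFrame({"y": y, "x": x, "g": g,
                         "hours": np.full(G * m, 2.0)})


class TestZTPoisson:
    def test_closed_form_pmf(self):
        # lam=1, y=1: e^-1 / (1 - e^-1) = 0.58198
        val = np.exp(ztpois_logpmf(np.array([1.0]), np.array([1.0])))[0]
        assert val == pytest.approx(0.5819767, abs=1e-6)

    def test_pmf_sums_to_one(self):
        lam = 2.7
        ys = np.arange(1, 60, dtype=float)
        total = np.exp(ztpois_logpmf(ys, np.full_like(ys, lam))).sum()
        assert total == pytest.approx(1.0, abs=1e-12)


class TestGLMLimit:
    def test_sigma_zero_poisson_matches_statsmodels_glm(self):
        df = _poisson_glmm_data(G=1, m=80)
        fit = fit_glmm(ModelSpec("y", "poisson", [Term("x")], groups=["g"]), df)
        glm = sm.GLM(df["y"], sm.add_constant(df["x"]),
                     family=sm.families.Poisson()).fit()
        assert fit.sigma2["g"] == 0.0 and fit.boundary
        assert fit.beta == pytest.approx(np.asarray(glm.params), abs=1e-6)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_offset_algebra(self):
        """Doubling every exposure shifts the intercept by -log 2 only."""
        df = _poisson_glmm_data(G=1, m=100)
        spec = ModelSpec("y", "poisson", [Term("x")], offset="hours")
        a = fit_glm(spec, df)
        df2 = df.assign(hours=df["hours"] * 2)
        b = fit_glm(spec, df2)
        assert b.coef("Intercept") == pytest.approx(
            a.coef("Intercept") - np.log(2), abs=1e-8)
        assert b.coef("x") == pytest.approx(a.coef("x"), abs=1e-8)


class TestGLMMRecovery:
    def test_poisson_recovery_within_2se(self):
        df = _poisson_glmm_data(G=200, m=20, seed=42)
        fit = fit_glmm(ModelSpec("y", "poisson", [Term("x")], groups=["g"]), df)
        assert fit.converged
        assert abs(fit.coef("Intercept") - 1.0) < 2 * fit.coef_se("Intercept")
        assert abs(fit.coef("x") - 0.3) < 2 * fit.coef_se("x")
        assert 0.1 < fit.sigma2["g"] < 0.5  # truth 0.25

    def test_matches_lme4_agq(self, tmp_path):
        """Independent oracle: lme4::glmer with nAGQ=15 on the same data."""
        df = _poisson_glmm_data(G=40, m=8, seed=3)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            d <- read.csv("{csv}")
            suppressMessages(library(lme4))
            m <- glmer(y ~ x + (1|g), data=d, family=poisson, nAGQ=15)
            cat(fixef(m), sqrt(diag(vcov(m))), unlist(VarCorr(m)), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        b0, b1, se0, se1, s2 = map(float, out.stdout.split())
        fit = fit_glmm(ModelSpec("y", "poisson", [Term("x")], groups=["g"]), df)
        assert fit.beta == pytest.approx([b0, b1], abs=2e-4)
        assert fit.se == pytest.approx([se0, se1], rel=2e-3)
        assert fit.sigma2["g"] == pytest.approx(s2, abs=2e-3)

    def test_crossed_binomial_recovery_within_2se(self):
        rng = np.random.default_rng(7)
        n = 3000
        f = rng.integers(0, 150, n)
        yr = rng.integers(0, 8, n)
        x = rng.binomial(1, 0.3, n).astype(float)
        bf = rng.normal(0, 0.6, 150)
        by = rng.normal(0, 0.3, 8)
        eta = -2.0 + np.log(2) * x + bf[f] + by[yr]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"y": y, "x": x, "f": f, "yr": yr})
        fit = fit_glmm(ModelSpec("y", "binomial", [Term("x")],
                                 groups=["f", "yr"]), df)
        assert abs(fit.coef("x") - np.log(2)) < 2 * fit.coef_se("x")
        assert abs(fit.coef("Intercept") + 2.0) < 2 * fit.coef_se("Intercept")

    def test_quadrature_insensitive_beyond_15_nodes(self):
        df = _poisson_glmm_data(G=30, m=6, seed=9)
        spec = ModelSpec("y", "poisson", [Term("x")], groups=["g"])
        f15 = fit_glmm(spec, df, n_nodes=15)
        f25 = fit_glmm(spec, df, n_nodes=25)
        assert f15.loglik == pytest.approx(f25.loglik, abs=1e-4)

    def test_loglik_dominates_null_model(self):
        df = _poisson_glmm_data(G=40, m=8, seed=1)
        full = fit_glmm(ModelSpec("y", "poisson", [Term("x")], groups=["g"]), df)
        null = fit_glmm(ModelSpec("y", "poisson", [], groups=["g"]), df)
        assert full.loglik >= null.loglik - 1e-6


class TestHurdle:
    def test_zero_probability_zero_reduces_to_pure_truncated(self):
        rng = np.random.default_rng(5)
        lam = 3.0
        y = rng.poisson(lam, 400)
        y = y[y > 0][:200]
        df = pd.DataFrame({"y": np.concatenate([y, [0] * 3]),
                           "g": np.tile(np.arange(7), 29)})
        h = fit_hurdle(ModelSpec("y", "ztpoisson", [], groups=["g"]), df)
        pos = df[df["y"] > 0]
        pure = fit_glmm(ModelSpec("y", "ztpoisson", [], groups=["g"]), pos)
        assert h.conditional.loglik == pytest.approx(pure.loglik, abs=1e-6)

    def test_degenerate_response_flagged(self):
        df = pd.DataFrame({"y": [1, 2, 3, 4], "g": [0, 0, 1, 1]})
        with pytest.raises(ValueError, match="zero"):
            fit_hurdle(ModelSpec("y", "ztpoisson", [], groups=["g"]), df)

    def test_recovery_within_2se(self):
        rng = np.random.default_rng(11)
        n, G = 2500, 120
        g = rng.integers(0, G, n)
        x = rng.normal(size=n)
        bz = rng.normal(0, 0.8, G)
        bc = rng.normal(0, 0.4, G)
        pzero = 1 / (1 + np.exp(-(-0.5 + 0.4 * x + bz[g])))
        lam = np.exp(0.8 + 0.3 * x + bc[g])
        iszero = rng.binomial(1, pzero)
        yc = rng.poisson(lam)
        while (yc == 0).any():
            redraw = yc == 0
            yc[redraw] = rng.poisson(lam[redraw])
        y = np.where(iszero == 1, 0, yc)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        h = fit_hurdle(ModelSpec("y", "ztpoisson", [Term("x")], groups=["g"]), df)
        z, c = h.zero, h.conditional
        assert abs(z.coef("x") - 0.4) < 2 * z.coef_se("x")
        assert abs(z.coef("Intercept") + 0.5) < 2 * z.coef_se("Intercept")
        assert abs(c.coef("x") - 0.3) < 2 * c.coef_se("x")
        assert abs(c.coef("Intercept") - 0.8) < 2 * c.coef_se("Intercept")
        assert 0.3 < z.sigma2["g"] < 1.3  # truth 0.64
        assert 0.05 < c.sigma2["g"] < 0.4  # truth 0.16


class TestWaldAndOR:
    def _fake_fit(self, names, beta, vcov, family="binomial"):
        beta = np.asarray(beta, float)
        vcov = np.asarray(vcov, float)
        slices = {n: slice(i, i + 1) for i, n in enumerate(names)}
        return FitResult(list(names), beta, np.sqrt(np.diag(vcov)), vcov, {},
                         0.0, True, False, family, 10, slices)

    def test_one_df_term_equals_squared_z(self):
        fit = self._fake_fit(["x"], [0.5], [[0.04]])
        chi2, df, p = wald_type3(fit, "x")
        assert chi2 == pytest.approx((0.5 / 0.2) ** 2)
        assert df == 1
        from scipy import stats
        assert p == pytest.approx(2 * stats.norm.sf(0.5 / 0.2), abs=1e-12)

    def test_zero_coefficient_gives_p_one(self):
        fit = self._fake_fit(["x"], [0.0], [[0.01]])
        chi2, _, p = wald_type3(fit, "x")
        assert chi2 == 0.0 and p == 1.0

    def test_block_term_matches_dense_quadratic_form(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        V = A @ A.T + np.eye(3)
        beta = rng.normal(size=3)
        slices = {"stage": slice(0, 3)}
        fit = FitResult(["a", "b", "c"], beta, np.sqrt(np.diag(V)), V, {},
                        0.0, True, False, "poisson", 10, slices)
        chi2, df, _ = wald_type3(fit, "stage")
        assert df == 3
        assert chi2 == pytest.approx(beta @ np.linalg.inv(V) @ beta, abs=1e-10)

    def test_odds_ratio_point_and_ci(self):
        fit = self._fake_fit(["v"], [0.70], [[0.14 ** 2]])
        orr, (lo, hi) = odds_ratio(fit, "v")
        assert round(orr, 2) == 2.01
        assert lo == pytest.approx(np.exp(0.70 - 1.96 * 0.14), abs=1e-9)
        assert hi == pytest.approx(np.exp(0.70 + 1.96 * 0.14), abs=1e-9)

    def test_odds_ratio_requires_binomial(self):
        fit = self._fake_fit(["v"], [0.1], [[0.01]], family="poisson")
        with pytest.raises(ValueError):
            odds_ratio(fit, "v")


class TestLMM:
    def test_no_groups_residuals_equal_ols(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 1 + 2 * df["x"] + rng.normal(size=50)
        fit, resid = fit_lmm(ModelSpec("y", "gaussian", [Term("x")]), df)
        X = np.column_stack([np.ones(50), df["x"]])
        beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert resid == pytest.approx(df["y"] - X @ beta_ols, abs=1e-8)

    def test_exact_linear_response_gives_zero_residuals(self):
        df = pd.DataFrame({"x": np.arange(30, dtype=float),
                           "g": np.repeat(np.arange(5), 6)})
        df["y"] = 3.0 - 0.5 * df["x"]
        _, resid = fit_lmm(ModelSpec("y", "gaussian", [Term("x")],
                                     groups=["g"]), df)
        assert np.allclose(resid, 0.0, atol=1e-6)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(14)
        G, m = 80, 8
        g = np.repeat(np.arange(G), m)
        x = rng.normal(size=G * m)
        b = rng.normal(0, 1.5, G)
        y = 2.0 + 0.8 * x + b[g] + rng.normal(0, 1.0, G * m)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        fit, _ = fit_lmm(ModelSpec("y", "gaussian", [Term("x")], groups=["g"]), df)
        assert abs(fit.coef("x") - 0.8) < 2 * fit.coef_se("x")
        assert 1.5 < fit.sigma2["g"] < 3.2  # truth 2.25

    def test_rank_deficient_design_names_aliased_column(self):
        df = pd.DataFrame({"x": np.arange(10, dtype=float)})
        df["x2"] = 2 * df["x"]
        df["y"] = df["x"]
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm(ModelSpec("y", "gaussian", [Term("x"), Term("x2")]), df)


class TestDesign:
    def test_factor_reference_level_honoured(self):
        df = pd.DataFrame({"stage": ["a", "b", "c", "b"], "y": [1, 2, 3, 4.0]})
        from nestprospect.glmm import build_design
        X, names, slices = build_design(
            ModelSpec("y", "poisson", [Term("stage", ref="b")]), df)
        assert names == ["Intercept", "stage[a]", "stage[c]"]
        assert X[:, 1].tolist() == [1, 0, 0, 0]

    def test_standardized_polynomial(self):
        df = pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0], "y": [1, 1, 1, 1.0]})
        from nestprospect.glmm import build_design
        X, names, _ = build_design(
            ModelSpec("y", "poisson",
                      [Term("age", degree=2, standardize=True)]), df)
        assert names == ["Intercept", "age", "age^2"]
        assert X[:, 1].mean() == pytest.approx(0.0)
        assert X[:, 1].std() == pytest.approx(1.0)
        assert X[:, 2] == pytest.approx(X[:, 1] ** 2)
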