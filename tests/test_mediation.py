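"""Path estimation, robust fitting, and bias-corrected bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from roimed import (
    MediationSpec,
    bootstrap_mediation,
    fit_paths,
    irls_bisquare,
    sobel_test,
)
from conftest import make_mediation_data


def _spec(**kw):
    base = dict(x="x", m="m", y="y", n_boot=200, seed=1)
    base.update(kw)
    return MediationSpec(**base)


class TestFitPaths:
    def test_near_deterministic_chain(self):
        # Y = M, M = X + vanishing noise: a -> 1, b -> 1, c -> 1, c' -> 0
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        m = x + 0.01 * rng.standard_normal(500)
        df = pd.DataFrame({"x": x, "m": m, "y": m})
        est = fit_paths(df, _spec())
        assert est.a == pytest.approx(1.0, abs=1e-3)
        assert est.b == pytest.approx(1.0, abs=1e-2)
        assert est.c == pytest.approx(1.0, abs=1e-3)
        assert est.c_prime == pytest.approx(0.0, abs=1e-2)
        assert est.ab == pytest.approx(1.0, abs=1e-2)

    def test_exactly_collinear_design_rejected_naming_columns(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "m": x, "y": x})
        with pytest.raises(ValueError, match="collinear"):
            fit_paths(df, _spec())

    def test_orthogonal_x_and_m(self):
        # fixed orthogonal mean-zero vectors: a = 0, c = 0, b = 1, ab = 0
        x = np.tile([1.0, -1.0], 8)
        m = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        df = pd.DataFrame({"x": x, "m": m, "y": m})
        est = fit_paths(df, _spec())
        assert est.a == pytest.approx(0.0, abs=1e-12)
        assert est.c == pytest.approx(0.0, abs=1e-12)
        assert est.b == pytest.approx(1.0, abs=1e-12)
        assert est.ab == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols_with_covariates(self):
        rng = np.random.default_rng(3)
        n = 80
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "m": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "z1": rng.standard_normal(n),
                "z2": rng.integers(0, 2, n).astype(float),
            }
        )
        spec = _spec(covariates=("z1", "z2"))
        est = fit_paths(df, spec)
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        zd = df.apply(z)
        X1 = sm.add_constant(zd[["x", "z1", "z2"]])
        X2 = sm.add_constant(zd[["x", "m", "z1", "z2"]])
        fit1 = sm.OLS(zd["m"], X1).fit()
        fit2 = sm.OLS(zd["y"], X2).fit()
        fit3 = sm.OLS(zd["y"], X1).fit()
        assert est.a == pytest.approx(fit1.params["x"], abs=1e-10)
        assert est.b == pytest.approx(fit2.params["m"], abs=1e-10)
        assert est.c_prime == pytest.approx(fit2.params["x"], abs=1e-10)
        assert est.c == pytest.approx(fit3.params["x"], abs=1e-10)
        assert est.se_a == pytest.approx(fit1.bse["x"], abs=1e-10)
        assert est.se_b == pytest.approx(fit2.bse["m"], abs=1e-10)

    def test_matches_pingouin_without_covariates(self):
        pingouin = pytest.importorskip("pingouin")
        df = make_mediation_data(150, a=0.5, b=0.4, c_prime=0.2, seed=4)
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        zd = df.apply(z)
        pg = pingouin.mediation_analysis(
            data=zd, x="x", m="m", y="y", n_boot=10, seed=0
        ).set_index("path")
        est = fit_paths(df, _spec())
        assert est.a == pytest.approx(pg.loc["m ~ X", "coef"], abs=1e-8)
        assert est.c == pytest.approx(pg.loc["Total", "coef"], abs=1e-8)
        assert est.c_prime == pytest.approx(pg.loc["Direct", "coef"], abs=1e-8)
        assert est.ab == pytest.approx(pg.loc["Indirect", "coef"], abs=1e-8)

    def test_decomposition_identity_nonrobust(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            n = int(rng.integers(20, 60))
            df = pd.DataFrame(
                rng.standard_normal((n, 4)), columns=["x", "m", "y", "z1"]
            )
            est = fit_paths(df, _spec(covariates=("z1",)))
            assert est.c == pytest.approx(est.c_prime + est.ab, abs=1e-10)
            assert est.ab == pytest.approx(est.a * est.b, abs=1e-12)

    def test_listwise_deletion(self):
        df = make_mediation_data(60, a=0.5, b=0.4, seed=6)
        df.loc[3, "m"] = np.nan
        est = fit_paths(df, _spec())
        assert est.n_used == 59

    def test_too_few_rows_rejected(self):
        df = make_mediation_data(4, a=0.5, b=0.4, seed=7).head(3)
        with pytest.raises(ValueError, match="complete rows"):
            fit_paths(df, _spec())


class TestSobel:
    def test_zero_a_gives_null(self):
        z, p = sobel_test(0.0, 0.5, 0.1, 0.1)
        assert z == 0.0 and p == 1.0

    def test_closed_form_symmetric_case(self):
        z, _ = sobel_test(1.0, 1.0, 1.0, 1.0)
        assert z == pytest.approx(1.0 / np.sqrt(2.0))

    def test_matches_textbook_formula_on_random_inputs(self):
        from scipy.stats import norm

        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b = rng.normal(size=2)
            se_a, se_b = rng.uniform(0.01, 1.0, 2)
            z, p = sobel_test(a, b, se_a, se_b)
            z_ref = a * b / np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
            assert z == pytest.approx(z_ref, rel=1e-12)
            assert p == pytest.approx(2 * (1 - norm.cdf(abs(z_ref))), rel=1e-9)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            sobel_test(0.5, 0.5, 0.0, 0.1)


class TestIrlsBisquare:
    def test_clean_gaussian_data_close_to_ols(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(200), rng.standard_normal(200)])
        y = X @ np.array([0.5, 1.5]) + 0.02 * rng.standard_normal(200)
        beta, converged = irls_bisquare(y, X)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert converged
        np.testing.assert_allclose(beta, ols, atol=1e-3)

    def test_matches_statsmodels_rlm(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = X @ np.array([1.0, 2.0]) + 0.3 * rng.standard_normal(100)
        y[:5] += rng.normal(20, 5, 5)
        beta, _ = irls_bisquare(y, X)
        rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(4.685)).fit(scale_est="mad")
        np.testing.assert_allclose(beta, rlm.params, atol=1e-4)

    def test_outlier_resistance_beats_ols(self):
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(100), rng.standard_normal(100)])
            y = X @ np.array([0.0, 1.0]) + 0.5 * rng.standard_normal(100)
            y[np.abs(X[:, 1]).argmax()] += 50.0  # gross outlier at a leverage point
            robust, _ = irls_bisquare(y, X)
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            if abs(robust[1] - 1.0) < abs(ols[1] - 1.0):
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_gross_outliers_get_exactly_zero_weight(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = X @ np.array([0.0, 1.0]) + 0.1 * rng.standard_normal(100)
        y[0] += 100.0
        beta, _ = irls_bisquare(y, X)
        resid = y - X @ beta
        scale = np.median(np.abs(resid)) / 0.6745
        u = resid / (4.685 * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        assert w[0] == 0.0
        # removing the zero-weight point reproduces the robust fit direction
        assert abs(beta[1] - 1.0) < 0.05

    def test_perfect_fit_short_circuits(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        y = X @ np.array([2.0, -1.0])
        beta, converged = irls_bisquare(y, X)
        assert converged
        np.testing.assert_allclose(beta, [2.0, -1.0], atol=1e-10)


class TestBootstrap:
    def test_seed_determinism(self):
        df = make_mediation_data(120, a=0.5, b=0.3, seed=12)
        spec = _spec(n_boot=300, seed=42, expected_sign_ab=1)
        r1 = bootstrap_mediation(df, spec)
        r2 = bootstrap_mediation(df, spec)
        assert r1 == r2

    def test_standardization_equivariance(self):
        df = make_mediation_data(150, a=0.5, b=0.3, seed=13)
        df["z1"] = np.random.default_rng(1).standard_normal(150)
        spec = _spec(covariates=("z1",), n_boot=300, seed=7, expected_sign_ab=1)
        r1 = bootstrap_mediation(df, spec)
        scaled = df.copy()
        scaled["m"] *= 37.5
        scaled["y"] *= 0.004
        r2 = bootstrap_mediation(scaled, spec)
        for f in ("beta_a", "beta_b", "beta_c", "beta_c_prime", "beta_ab"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-10)
        for f in ("p_a", "p_b", "p_c", "p_c_prime", "p_ab"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-10)

    def test_strong_effect_detected_one_tailed(self):
        df = make_mediation_data(400, a=0.5, b=0.4, seed=14)
        res = bootstrap_mediation(df, _spec(n_boot=1000, expected_sign_ab=1, seed=3))
        assert res.p_ab < 0.01
        assert res.ci_ab[0] > 0
        assert res.n_boot_effective == 1000

    def test_wrong_declared_direction_gives_large_p(self):
        df = make_mediation_data(400, a=0.5, b=0.4, seed=15)  # true ab > 0
        res = bootstrap_mediation(df, _spec(n_boot=500, expected_sign_ab=-1, seed=3))
        assert res.p_ab >= 0.5

    def test_two_tailed_doubles_one_tailed(self):
        df = make_mediation_data(200, a=0.4, b=0.15, seed=16)
        one = bootstrap_mediation(df, _spec(n_boot=800, expected_sign_ab=1, seed=5))
        two = bootstrap_mediation(df, _spec(n_boot=800, tails="two", seed=5))
        assert two.p_ab == pytest.approx(min(1.0, 2 * one.p_ab), abs=5e-4)

    def test_robust_and_ols_agree_on_clean_data(self):
        df = make_mediation_data(250, a=0.5, b=0.4, seed=17)
        ols = bootstrap_mediation(df, _spec(n_boot=100, expected_sign_ab=1, seed=2))
        rob = bootstrap_mediation(
            df, _spec(n_boot=100, robust=True, expected_sign_ab=1, seed=2)
        )
        assert rob.beta_ab == pytest.approx(ols.beta_ab, abs=0.03)
        assert rob.p_ab < 0.05

    def test_degenerate_covariate_aborts_with_diagnostic(self):
        df = make_mediation_data(15, a=0.5, b=0.4, seed=18)
        df["z1"] = 0.0
        df.loc[0, "z1"] = 1.0  # resamples missing row 0 make z1 constant
        with pytest.raises(RuntimeError, match="10%"):
            bootstrap_mediation(df, _spec(covariates=("z1",), n_boot=400, seed=1))

    def test_bootstrap_sd_positive_and_mean_near_estimate(self):
        df = make_mediation_data(300, a=0.5, b=0.4, seed=19)
        res = bootstrap_mediation(df, _spec(n_boot=800, expected_sign_ab=1, seed=4))
        assert res.boot_ab_sd > 0
        assert res.boot_ab_mean == pytest.approx(res.beta_ab, abs=4 * res.boot_ab_sd)
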