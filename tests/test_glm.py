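import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcpipe.design import (
    DesignEncoder,
    body_condition_residuals,
    parse_model,
    standardize_2sd,
)
from hfcpipe.glm import (
    FitResult,
    aicc,
    fit_gaussian,
    fit_negbin,
    nb_deviance,
    refit_negbin_fixed_theta,
)

CATS = {
    "month": ["April", "May", "June", "July", "August"],
    "area": ["A1", "A2", "A3", "A4", "A5", "A6"],
    "age": ["I", "II", "III", "IV"],
    "sex": ["Female", "Male"],
    "aggregation": ["no", "yes"],
    "food": ["no", "yes"],
    "year": ["2006", "2007"],
}


def _covariate_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "month": rng.choice(CATS["month"], n),
            "area": rng.choice(CATS["area"], n),
            "age": rng.choice(CATS["age"], n),
            "sex": rng.choice(CATS["sex"], n),
            "aggregation": rng.choice(CATS["aggregation"], n),
            "food": rng.choice(CATS["food"], n),
            "year": rng.choice(CATS["year"], n),
            "condition": rng.normal(size=n),
        }
    )
    df["IR"], _, _ = standardize_2sd(rng.normal(size=n))
    return df


class TestStandardize2SD:
    def test_hand_case(self):
        out, mean, sd = standardize_2sd([0.0, 1.0, 2.0])
        assert mean == 1.0 and sd == 1.0
        assert out.tolist() == [-0.5, 0.0, 0.5]

    def test_mean_zero_sd_half(self):
        rng = np.random.default_rng(1)
        out, _, _ = standardize_2sd(rng.gamma(2, 3, size=500))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=1) - 0.5) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        once, _, _ = standardize_2sd(rng.normal(size=100))
        twice, _, _ = standardize_2sd(once)
        assert np.allclose(once, twice)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            standardize_2sd([3.0, 3.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=60,
        ).filter(lambda xs: np.std(xs, ddof=1) > 1e-3)
    )
    def test_invariants_for_arbitrary_inputs(self, xs):
        out, _, _ = standardize_2sd(xs)
        assert abs(out.mean()) < 1e-7
        assert abs(out.std(ddof=1) - 0.5) < 1e-7


class TestDesignEncoding:
    def test_month_dummies_drop_reference(self):
        df = _covariate_frame(200)
        spec = parse_model("y ~ month", "gaussian", CATS)
        X = DesignEncoder(spec).fit_transform(df)
        assert [c for c in X.columns if c.startswith("month")] == [
            "month[May]", "month[June]", "month[July]", "month[August]",
        ]

    def test_interaction_column_count(self):
        df = _covariate_frame(200)
        spec = parse_model("y ~ age + sex + age*sex", "gaussian", CATS)
        X = DesignEncoder(spec).fit_transform(df)
        inter = [c for c in X.columns if "*" in c]
        assert len(inter) == 3  # 3 age dummies x 1 sex dummy

    def test_quadratic_column_is_standardized(self):
        df = _covariate_frame(300)
        spec = parse_model("y ~ IR + IR^2", "gaussian", CATS)
        X = DesignEncoder(spec).fit_transform(df)
        assert abs(X["IR"].std(ddof=1) - 0.5) < 1e-9
        assert abs(X["IR^2"].std(ddof=1) - 0.5) < 1e-9
        assert abs(X["IR^2"].mean()) < 1e-9

    def test_unseen_level_rejected_at_prediction(self):
        df = _covariate_frame(50)
        spec = parse_model("y ~ sex", "gaussian", {"sex": ["Female", "Male"]})
        enc = DesignEncoder(spec).fit(df)
        bad = df.copy()
        bad.loc[bad.index[0], "sex"] = "Unknown"
        with pytest.raises(ValueError, match="Unknown"):
            enc.transform(bad)


class TestGaussianFit:
    def test_noiseless_slope_recovery(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 30)})
        df["y"] = 2.0 * df["x"]
        fit = fit_gaussian(parse_model("y ~ x", "gaussian"), df)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)

    def test_intercept_only_matches_closed_form(self):
        rng = np.random.default_rng(3)
        y = rng.normal(5, 2, size=40)
        df = pd.DataFrame({"y": y})
        fit = fit_gaussian(parse_model("y ~ 1", "gaussian"), df)
        assert fit.params["const"] == pytest.approx(y.mean())
        n = len(y)
        rss = np.sum((y - y.mean()) ** 2)
        assert fit.llf == pytest.approx(-n / 2 * (np.log(2 * np.pi * rss / n) + 1), abs=1e-9)
        assert fit.k == 2  # intercept + sigma^2

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        df = _covariate_frame(120, seed=4)
        df["y"] = rng.normal(size=120)
        spec = parse_model("y ~ month + IR + IR^2 + condition", "gaussian", CATS)
        fit = fit_gaussian(spec, df)
        X = DesignEncoder(spec).fit_transform(df).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_collinear_design_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "z": [2.0, 4, 6, 8], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="collinear"):
            fit_gaussian(parse_model("y ~ x + z", "gaussian"), df)


class TestNegativeBinomialFit:
    def test_intercept_only_is_log_mean(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.poisson(7, size=200)})
        fit = fit_negbin(parse_model("y ~ 1", "negbin"), df)
        assert fit.params["const"] == pytest.approx(np.log(df["y"].mean()), abs=1e-6)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(6)
        n = 5000
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.5 * x)
        y = rng.poisson(rng.gamma(2.0, mu / 2.0))
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_negbin(parse_model("y ~ x", "negbin"), df)
        assert abs(fit.params["const"] - 1.0) < 3 * fit.bse["const"]
        assert abs(fit.params["x"] - 0.5) < 3 * fit.bse["x"]
        assert fit.dispersion == pytest.approx(2.0, rel=0.25)
        assert fit.converged

    def test_equidispersed_data_flags_theta_boundary(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.poisson(10, size=800)})
        fit = fit_negbin(parse_model("y ~ 1", "negbin"), df)
        assert fit.dispersion > 50
        assert fit.theta_boundary

    def test_matches_joint_ml_cross_check(self):
        # independent route: statsmodels' joint-ML discrete NegativeBinomial
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 1500
        x = rng.normal(size=n)
        y = rng.poisson(rng.gamma(1.5, np.exp(0.8 + 0.4 * x) / 1.5))
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_negbin(parse_model("y ~ x", "negbin"), df)
        X = np.column_stack([np.ones(n), x])
        ref = sm.NegativeBinomial(y, X).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), ref.params[:2], atol=1e-3)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-2)

    def test_non_integer_response_rejected(self):
        df = pd.DataFrame({"y": [1.5, 2.0, 3.0, 1.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="integer"):
            fit_negbin(parse_model("y ~ 1", "negbin"), df)

    def test_deviance_non_increasing_with_added_term(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.normal(size=n)
        y = rng.poisson(rng.gamma(1.5, np.exp(1.0 + 0.3 * x) / 1.5))
        df = pd.DataFrame({"x": x, "z": rng.normal(size=n), "y": y})
        big = fit_negbin(parse_model("y ~ x + z", "negbin"), df)
        # compare at the larger model's theta
        small = refit_negbin_fixed_theta(parse_model("y ~ x", "negbin"), df, big.dispersion)
        assert big.deviance <= small.deviance + 1e-8


class TestAICc:
    def test_reference_table_inputs(self):
        fit = FitResult("m", "negbin", pd.Series(dtype=float), pd.Series(dtype=float),
                        llf=-460.03, k=14, nobs=259, deviance=0.0, df_resid=0,
                        dispersion=1.0, converged=True)
        assert aicc(fit) == pytest.approx(949.78, abs=0.005)

    def test_small_case(self):
        fit = FitResult("m", "gaussian", pd.Series(dtype=float), pd.Series(dtype=float),
                        llf=0.0, k=1, nobs=10, deviance=0.0, df_resid=9,
                        dispersion=1.0, converged=True)
        assert aicc(fit) == pytest.approx(2.5)

    def test_large_n_limit_approaches_aic(self):
        fit = FitResult("m", "gaussian", pd.Series(dtype=float), pd.Series(dtype=float),
                        llf=-100.0, k=5, nobs=10**7, deviance=0.0, df_resid=0,
                        dispersion=1.0, converged=True)
        assert aicc(fit) == pytest.approx(2 * 100 + 2 * 5, abs=1e-4)

    def test_undefined_when_n_too_small(self):
        fit = FitResult("m", "gaussian", pd.Series(dtype=float), pd.Series(dtype=float),
                        llf=0.0, k=5, nobs=6, deviance=0.0, df_resid=1,
                        dispersion=1.0, converged=True)
        with pytest.raises(ValueError):
            aicc(fit)


class TestBodyCondition:
    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(10)
        size = rng.normal(60, 5, 50)
        mass = 2 + 0.1 * size + rng.normal(0, 1, 50)
        assert abs(body_condition_residuals(mass, size).sum()) < 1e-9

    def test_perfectly_linear_mass(self):
        size = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(body_condition_residuals(2 + 3 * size, size), 0.0)

    def test_three_point_hand_case(self):
        res = body_condition_residuals([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert np.allclose(res, [1 / 6, -1 / 3, 1 / 6])

    def test_zero_size_variance_rejected(self):
        with pytest.raises(ValueError):
            body_condition_residuals([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def test_k_bookkeeping_for_reference_model_forms():
    # e.g. Aggregation+Food+Month+Area: 1+1+1+4+5 coefficients + theta = 13
    df = _covariate_frame(300, seed=11)
    spec = parse_model("y ~ aggregation + food + month + area", "negbin", CATS)
    X = DesignEncoder(spec).fit_transform(df)
    assert X.shape[1] + 1 == 13
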