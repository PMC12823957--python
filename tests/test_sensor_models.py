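"""Design construction, OLS statistics panel, prediction, serialization."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripsensors import (
    ModelKind,
    SensorModel,
    build_design,
    fit_ols,
    fit_sensor_model,
    load_model,
    predict,
    save_model,
)
from ripsensors.errors import (
    CollinearityError,
    ConfigurationError,
    CorruptModelError,
    UnderdeterminedFitError,
)
from ripsensors.sensor_models import CoefStats, FitStats


def normal_equations_oracle(X, y):
    """Independent closed-form OLS: beta, SE, t, R2, F via explicit inverses."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sse = resid @ resid
    sst = np.sum((y - y.mean()) ** 2)
    dof = n - p
    se = np.sqrt(np.diag(xtx_inv) * sse / dof)
    t = beta / se
    r2 = 1 - sse / sst
    f = ((sst - sse) / (p - 1)) / (sse / dof)
    return beta, se, t, r2, f


def _hr_rows(n=40, seed=0, noise=0.0, beta=None):
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta if beta is not None else [65, 3, 1, 5, -2, -0.8], float)
    cols = {
        "Xband1": rng.lognormal(size=n),
        "Xband2": rng.lognormal(size=n),
        "Xband3": rng.lognormal(size=n),
        "RMS": rng.lognormal(size=n),
        "Skewness": rng.normal(0, 0.5, size=n),
    }
    X = np.column_stack([np.ones(n)] + [cols[c] for c in cols])
    cols["target_pulse"] = X @ beta + noise * rng.standard_normal(n)
    return pd.DataFrame(cols), beta


class TestBuildDesign:
    def test_hr_design_shape_and_constant_column(self):
        rows, _ = _hr_rows(10)
        X, y, names = build_design(rows, ModelKind.HR)
        assert X.shape == (10, 6)
        np.testing.assert_array_equal(X[:, 0], 1.0)
        assert names == ("Intercept", "Xband1", "Xband2", "Xband3", "RMS", "Skewness")

    def test_two_predictor_design_shape(self):
        rows = pd.DataFrame(
            {"XAB": np.arange(10.0), "XTH": np.arange(10.0) ** 2, "target_npf_mag": np.ones(10)}
        )
        X, y, names = build_design(rows, ModelKind.NPF)
        assert X.shape == (10, 3)
        assert names == ("Intercept", "XAB", "XTH")

    def test_missing_predictor_column_errors(self):
        rows = pd.DataFrame({"XNPF": np.arange(10.0), "target_pes_mag": np.ones(10)})
        with pytest.raises(ConfigurationError, match="XOPF"):
            build_design(rows, ModelKind.PES1)

    def test_too_few_rows_errors(self):
        rows, _ = _hr_rows(6)
        with pytest.raises(UnderdeterminedFitError):
            build_design(rows, ModelKind.HR)


class TestFitOls:
    def test_exact_linear_relation_recovered(self):
        x = np.linspace(0, 5, 20)
        X = np.column_stack([np.ones(20), x])
        beta, coef_stats, fit_stats = fit_ols(X, 2 + 3 * x)
        np.testing.assert_allclose(beta, [2.0, 3.0], atol=1e-10)
        assert fit_stats.r2 == pytest.approx(1.0)
        assert fit_stats.residual_rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_target_gives_zero_slopes_and_r2(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(15), rng.standard_normal((15, 2))])
        beta, _, fit_stats = fit_ols(X, np.full(15, 7.0))
        np.testing.assert_allclose(beta, [7.0, 0.0, 0.0], atol=1e-10)
        assert fit_stats.r2 == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            X = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
            y = rng.standard_normal(30)
            beta, coef_stats, fit_stats = fit_ols(X, y)
            b0, se0, t0, r20, f0 = normal_equations_oracle(X, y)
            np.testing.assert_allclose(beta, b0, rtol=1e-8)
            np.testing.assert_allclose([c.se for c in coef_stats], se0, rtol=1e-8)
            np.testing.assert_allclose([c.t_stat for c in coef_stats], t0, rtol=1e-8)
            assert fit_stats.r2 == pytest.approx(r20, rel=1e-8)
            assert fit_stats.f_vs_constant == pytest.approx(f0, rel=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        y = X @ np.array([1.0, 0.5, -0.2, 0.0]) + rng.standard_normal(50)
        beta, coef_stats, fit_stats = fit_ols(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta, ref.params, rtol=1e-9)
        np.testing.assert_allclose([c.se for c in coef_stats], ref.bse, rtol=1e-9)
        np.testing.assert_allclose([c.p_value for c in coef_stats], ref.pvalues, rtol=1e-8)
        assert fit_stats.r2 == pytest.approx(ref.rsquared, rel=1e-9)
        assert fit_stats.adj_r2 == pytest.approx(ref.rsquared_adj, rel=1e-9)
        assert fit_stats.f_vs_constant == pytest.approx(ref.fvalue, rel=1e-9)
        assert fit_stats.f_p_value == pytest.approx(ref.f_pvalue, rel=1e-8)

    def test_error_dof_definition(self):
        rows, _ = _hr_rows(40)
        model = fit_sensor_model(rows, ModelKind.HR)
        assert model.fit_stats.error_dof == 40 - 6

    def test_residuals_orthogonal_to_design(self, rng):
        X = np.column_stack([np.ones(60), rng.standard_normal((60, 3))])
        y = rng.standard_normal(60)
        beta, _, _ = fit_ols(X, y)
        resid = y - X @ beta
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_collinearity_names_dependent_column(self):
        x = np.linspace(1, 2, 20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(CollinearityError):
            fit_ols(X, np.ones(20), names=("Intercept", "a", "a_copy"))

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        for _ in range(20):
            X = np.column_stack([np.ones(25), rng.standard_normal((25, 4))])
            y = rng.standard_normal(25)
            _, _, fs = fit_ols(X, y)
            assert fs.adj_r2 <= fs.r2 + 1e-12


class TestPredict:
    def test_zero_predictors_give_intercept(self):
        rows, beta = _hr_rows(20)
        model = fit_sensor_model(rows, ModelKind.HR)
        zero = pd.DataFrame({c: np.zeros(3) for c in rows.columns if c != "target_pulse"})
        np.testing.assert_allclose(predict(model, zero), model.coefficients[0])

    def test_training_rows_of_exact_fit_reproduce_target(self):
        rows, _ = _hr_rows(30, noise=0.0)
        model = fit_sensor_model(rows, ModelKind.HR)
        np.testing.assert_allclose(predict(model, rows), rows.target_pulse, rtol=1e-8)

    def test_matches_explicit_dot_product(self, rng):
        rows, _ = _hr_rows(12, noise=1.0, seed=5)
        model = fit_sensor_model(rows, ModelKind.HR)
        yhat = predict(model, rows)
        for i in range(len(rows)):
            manual = model.coefficients[0] + sum(
                model.coefficients[j] * rows.iloc[i][name]
                for j, name in enumerate(model.coefficient_names[1:], start=1)
            )
            assert yhat[i] == pytest.approx(manual, rel=1e-12)


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path):
        rows, _ = _hr_rows(25, noise=0.5)
        model = fit_sensor_model(rows, ModelKind.HR, feature_conventions={"epoch_seconds": 60.0})
        path = save_model(model, tmp_path / "hr.json")
        back = load_model(path)
        assert back.kind == model.kind
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.fit_stats == model.fit_stats
        assert back.feature_conventions == model.feature_conventions

    def test_coefficient_count_mismatch_rejected(self, tmp_path):
        rows, _ = _hr_rows(25)
        model = fit_sensor_model(rows, ModelKind.HR)
        path = save_model(model, tmp_path / "hr.json")
        payload = json.loads(path.read_text())
        payload["coefficients"] = payload["coefficients"][:4]
        payload["coefficient_names"] = payload["coefficient_names"][:4]
        payload["coef_stats"] = payload["coef_stats"][:4]
        path.write_text(json.dumps(payload))
        with pytest.raises(CorruptModelError):
            load_model(path)

    def test_hand_written_model_predicts_accordingly(self, tmp_path):
        payload = {
            "kind": "NPF",
            "coefficient_names": ["Intercept", "XAB", "XTH"],
            "coefficients": [1.0, 2.0, -0.5],
            "coef_stats": [{"se": 0.0, "t_stat": 0.0, "p_value": 1.0}] * 3,
            "fit_stats": {
                "n_obs": 10, "error_dof": 7, "r2": 0.5, "adj_r2": 0.4,
                "f_vs_constant": 3.0, "f_p_value": 0.1, "residual_rmse": 0.2,
            },
            "feature_conventions": {},
        }
        path = tmp_path / "npf.json"
        path.write_text(json.dumps(payload))
        model = load_model(path)
        rows = pd.DataFrame({"XAB": [1.0, 0.0], "XTH": [2.0, 4.0]})
        np.testing.assert_allclose(predict(model, rows), [1 + 2 - 1, 1 - 2])


class TestCoverageOfStandardErrors:
    def test_true_coefficients_within_three_se(self, rng):
        """Classical SE calibration: ~99.7% per-coefficient 3-sigma coverage."""
        hits = total = 0
        for rep in range(100):
            rows, beta = _hr_rows(120, seed=rep, noise=1.0)
            model = fit_sensor_model(rows, ModelKind.HR)
            se = np.array([c.se for c in model.coef_stats])
            hits += int(np.sum(np.abs(model.coefficients - beta) <= 3 * se))
            total += beta.size
        assert hits / total >= 0.99
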