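import numpy as np
import pandas as pd
import pytest

from qbd.design import DesignTable, FactorSpec, build_bbd
from qbd.rsm import (
    adequate_precision,
    fit_model,
    model_terms,
    predict,
    press_and_pred_r2,
    select_model,
    term_matrix,
)
from qbd.simulate import TrueSurface, simulate_bbd_study

SPECS = [FactorSpec("A", -1, 1), FactorSpec("B", -1, 1), FactorSpec("C", -1, 1)]


def _with_response(name, y, specs=None, table=None):
    table = table if table is not None else build_bbd(specs or SPECS, n_center=3)
    return table.with_responses(pd.DataFrame({name: y}, index=table.coded.index))


class TestFitModel:
    """The coded least-squares fits behind the study's regression equations."""

    @pytest.mark.parametrize(
        "response, order, term, expected",
        [
            # entrapment efficiency, quadratic
            ("EE_pct", "quadratic", "Intercept", 62.94),
            ("EE_pct", "quadratic", "PLGA", 9.54),
            ("EE_pct", "quadratic", "PVA", 4.60),
            ("EE_pct", "quadratic", "Vaq", -9.13),
            # particle size, main effects
            ("size_nm", "linear", "PLGA", 63.52),
            ("size_nm", "linear", "PVA", -59.19),
            ("size_nm", "linear", "Vaq", 49.19),
            # 8-h release, quadratic
            ("Q8h_pct", "quadratic", "PVA", 12.34),
            ("Q8h_pct", "quadratic", "Intercept", 46.12),
            # 24-h permeation, main effects
            ("Q24_ug_cm2", "linear", "Intercept", 318.12),
            ("Q24_ug_cm2", "linear", "PLGA", -87.25),
        ],
    )
    def test_study_coefficients_match_reported_equations(
        self, study, response, order, term, expected
    ):
        model = fit_model(study, response, order)
        assert model.coef(term) == pytest.approx(expected, abs=0.01)

    def test_constant_response_gives_pure_intercept(self):
        table = _with_response("Y", np.full(15, 7.5))
        model = fit_model(table, "Y", "quadratic")
        assert model.coef("Intercept") == pytest.approx(7.5, abs=1e-9)
        others = [v for k, v in model.coefficients.items() if k != "Intercept"]
        assert np.allclose(others, 0, atol=1e-9)

    def test_main_effects_intercept_is_grand_mean(self, study):
        for response in ["size_nm", "Q24_ug_cm2"]:
            model = fit_model(study, response, "linear")
            assert model.coef("Intercept") == pytest.approx(
                study.response(response).mean(), abs=1e-9
            )

    def test_main_effects_equal_orthogonal_contrasts(self, study):
        """On a BBD each main effect is sum(x*y)/8 over the non-zero runs."""
        X = study.coded.to_numpy()
        for response in ["EE_pct", "size_nm", "Q8h_pct", "Q24_ug_cm2"]:
            y = study.response(response)
            model = fit_model(study, response, "quadratic")
            for j, name in enumerate(study.factor_names):
                assert model.coef(name) == pytest.approx(X[:, j] @ y / 8.0, abs=1e-9)

    def test_fitted_plus_residual_is_observed(self, study):
        model = fit_model(study, "EE_pct", "quadratic")
        np.testing.assert_allclose(
            model.fitted + model.residuals, study.response("EE_pct"), atol=1e-9
        )

    def test_rank_deficient_design_names_collinear_terms(self):
        coded = build_bbd(SPECS, n_center=3).coded.copy()
        coded["C"] = coded["B"]  # perfectly collinear factors
        table = DesignTable(SPECS, coded).with_responses(
            pd.DataFrame({"Y": np.arange(15.0)}, index=coded.index)
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_model(table, "Y", "linear")

    def test_missing_response_cells_rejected(self):
        y = np.arange(15.0)
        y[4] = np.nan
        table = _with_response("Y", y)
        with pytest.raises(ValueError, match="missing"):
            fit_model(table, "Y", "linear")

    def test_noiseless_surface_recovered_to_machine_precision(self):
        truth = {
            "Intercept": 60.0, "A": 9.5, "B": 4.6, "C": -9.1,
            "A:B": -3.8, "A:C": 7.2, "B:C": -4.5,
            "A^2": 11.2, "B^2": 9.7, "C^2": 5.3,
        }
        table = simulate_bbd_study(SPECS, 3, TrueSurface(truth, noise_sd=0.0))
        model = fit_model(table, "Y", "quadratic")
        for term, value in truth.items():
            assert model.coef(term) == pytest.approx(value, abs=1e-9)


class TestDiagnostics:
    def test_study_ee_fit_statistics(self, study):
        stats = fit_model(study, "EE_pct", "quadratic").stats
        assert stats.adj_r2 == pytest.approx(0.9395, abs=0.01)
        assert stats.pred_r2 == pytest.approx(0.6813, abs=0.01)
        assert stats.adequate_precision == pytest.approx(15.05, abs=0.01)

    @pytest.mark.parametrize(
        "response, order, expected_ap",
        [("Q8h_pct", "quadratic", 11.204), ("size_nm", "linear", 9.889)],
    )
    def test_study_adequate_precision(self, study, response, order, expected_ap):
        model = fit_model(study, response, order)
        assert adequate_precision(model) == pytest.approx(expected_ap, abs=0.01)

    def test_press_matches_explicit_leave_one_out_refits(self, study):
        """Leverage-form PRESS equals brute-force LOO refitting."""
        for table, response, order in [
            (study, "EE_pct", "quadratic"),
            (study, "size_nm", "linear"),
        ]:
            X, _ = term_matrix(table.coded.to_numpy(), table.factor_names, order)
            y = table.response(response)
            press_loo = 0.0
            for i in range(len(y)):
                keep = np.arange(len(y)) != i
                beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
                press_loo += (y[i] - X[i] @ beta) ** 2
            press, pred_r2 = press_and_pred_r2(fit_model(table, response, order))
            assert press == pytest.approx(press_loo, rel=1e-9)
            sst = np.sum((y - y.mean()) ** 2)
            assert pred_r2 == pytest.approx(1 - press_loo / sst, rel=1e-9)

    def test_toy_five_point_press_against_loo_oracle(self):
        x = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        y = np.array([1.0, 2.2, 2.9, 4.1, 5.3])
        X = np.column_stack([np.ones(5), x])
        hat = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        press_lev = np.sum((resid / (1 - hat)) ** 2)
        press_loo = 0.0
        for i in range(5):
            keep = np.arange(5) != i
            beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            press_loo += (y[i] - X[i] @ beta) ** 2
        assert press_lev == pytest.approx(press_loo, rel=1e-12)

    def test_noiseless_linear_data_has_unit_predicted_r2(self):
        table = build_bbd(SPECS, n_center=3)
        X = table.coded.to_numpy()
        y = 5.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1] + 0.5 * X[:, 2]
        table = _with_response("Y", y, table=table)
        _, pred_r2 = press_and_pred_r2(fit_model(table, "Y", "linear"))
        assert pred_r2 == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_r2_never_exceeds_r2_and_press_bounds_sse(self, study):
        for response in ["EE_pct", "size_nm", "Q8h_pct", "Q24_ug_cm2"]:
            for order in ["linear", "2FI", "quadratic"]:
                stats = fit_model(study, response, order).stats
                assert stats.adj_r2 <= stats.r2 + 1e-12
                model = fit_model(study, response, order)
                sse = float(model.residuals @ model.residuals)
                assert stats.press >= sse - 1e-9

    def test_zero_mse_rejected_for_adequate_precision(self):
        table = _with_response("Y", np.zeros(15))
        with pytest.raises(ValueError, match="MSE"):
            adequate_precision(fit_model(table, "Y", "linear"))


class TestPredict:
    def test_center_point_returns_intercept(self, study):
        model = fit_model(study, "EE_pct", "quadratic")
        assert predict(model, [0, 0, 0]) == pytest.approx(model.coef("Intercept"))

    def test_linear_vertex_is_intercept_plus_main_effect(self, study):
        model = fit_model(study, "Q24_ug_cm2", "linear")
        expected = model.coef("Intercept") + model.coef("PLGA")
        assert predict(model, [1, 0, 0]) == pytest.approx(expected)

    def test_quadratic_ee_prediction_at_study_optimum(self, study):
        """The fitted surface evaluated at the reported optimal formulation."""
        model = fit_model(study, "EE_pct", "quadratic")
        assert predict(model, [-1.0, 0.7, -1.0]) == pytest.approx(99.87, abs=0.25)

    def test_dimension_mismatch_rejected(self, study):
        model = fit_model(study, "EE_pct", "quadratic")
        with pytest.raises(ValueError, match="coded coordinates"):
            predict(model, [0.0, 0.0])

    def test_extrapolation_warns_but_evaluates(self, study):
        model = fit_model(study, "EE_pct", "quadratic")
        with pytest.warns(UserWarning, match="extrapolation"):
            predict(model, [1.5, 0.0, 0.0])


class TestSelectModel:
    def test_quadratic_surface_selected_from_simulation(self):
        truth = {"Intercept": 50.0, "A": 8.0, "B": 5.0, "C": -6.0,
                 "A^2": 12.0, "B^2": -9.0, "C^2": 10.0}
        table = simulate_bbd_study(SPECS, 3, TrueSurface(truth, noise_sd=0.5, seed=11))
        assert select_model(table, "Y") == "quadratic"

    def test_intercept_only_data_selects_linear(self):
        rng = np.random.default_rng(3)
        table = _with_response("Y", 10.0 + rng.normal(0, 1.0, 15))
        assert select_model(table, "Y") == "linear"

    def test_study_entrapment_selects_quadratic(self, study):
        assert select_model(study, "EE_pct") == "quadratic"

    def test_terms_ladder_sizes(self):
        assert len(model_terms(["A", "B", "C"], "linear")) == 4
        assert len(model_terms(["A", "B", "C"], "2FI")) == 7
        assert len(model_terms(["A", "B", "C"], "quadratic")) == 10
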