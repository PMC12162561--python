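"""Ridge, SVR and network predictors vs. independent oracles."""

import numpy as np
import pytest

from lagrisk import (
    KernelSVRModel,
    LagNetworkModel,
    NetworkTrainingConfig,
    RidgeLagModel,
    diagnose,
    feature_importance,
    network_fit,
    ridge_fit,
    svr_select,
)
from lagrisk.panel import LAG_COLUMNS

from conftest import make_incidence


class TestRidge:
    def test_k_zero_equals_ols(self, default_panel, default_incidence):
        """At k = 0 ridge reduces to the least-squares fit."""
        res = ridge_fit(default_panel, default_incidence, k=0.0)
        X = default_panel.sort_values(["region_id", "year"])[LAG_COLUMNS].to_numpy()
        y = default_incidence.sort_values(["region_id", "year"])["incidence"].to_numpy()
        A = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(res.coefficients_original.to_numpy(), beta[1:], atol=1e-8)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(res.predictions, A @ beta, atol=1e-8)

    def test_extreme_k_shrinks_coefficients_to_zero(self, default_panel, default_incidence):
        res = ridge_fit(default_panel, default_incidence, k=1e9)
        assert np.linalg.norm(res.coefficients) < 1e-3

    def test_matches_sklearn_ridge_at_k_100(self, default_panel, default_incidence):
        """Independent solver oracle: sklearn Ridge on the standardized data."""
        from sklearn.linear_model import Ridge

        model = RidgeLagModel(default_panel, default_incidence)
        res = model.fit(k=100.0)
        oracle = Ridge(alpha=100.0, fit_intercept=False).fit(model.Xs, model.ys)
        np.testing.assert_allclose(res.coefficients.to_numpy(), oracle.coef_, atol=1e-8)

    def test_modified_vif_at_k_zero_equals_ordinary_vif(self, default_panel, default_incidence):
        res = ridge_fit(default_panel, default_incidence, k=0.0)
        ordinary = diagnose(default_panel).vif
        np.testing.assert_allclose(res.modified_vif, ordinary, atol=1e-6)

    def test_modified_vif_controlled_at_large_k(self, default_panel, default_incidence):
        """Larger penalties can only reduce the worst variance inflation."""
        model = RidgeLagModel(default_panel, default_incidence)
        trace = model.trace([0.0, 1.0, 10.0, 100.0])
        assert trace["max_modified_vif"].iloc[-1] <= trace["max_modified_vif"].iloc[0]

    def test_trace_monotonicity(self, default_panel, default_incidence):
        """Standardized in-sample MSE never decreases, coefficient norm never
        grows, along an ascending k grid."""
        trace = RidgeLagModel(default_panel, default_incidence).trace(
            [0.0, 0.5, 1.0, 10.0, 100.0, 1000.0]
        )
        assert (np.diff(trace["mse_standardized"]) >= -1e-12).all()
        assert (np.diff(trace["coef_norm"]) <= 1e-12).all()

    def test_singleton_grid_equals_single_fit(self, default_panel, default_incidence):
        model = RidgeLagModel(default_panel, default_incidence)
        trace = model.trace([0.0])
        res = model.fit(0.0)
        assert len(trace) == 1
        assert trace["mse"].iloc[0] == pytest.approx(res.mse)

    def test_unsorted_grid_sorted_with_warning(self, default_panel, default_incidence, caplog):
        import logging

        model = RidgeLagModel(default_panel, default_incidence)
        with caplog.at_level(logging.WARNING):
            trace = model.trace([10.0, 0.0, 1.0])
        assert list(trace["k"]) == [0.0, 1.0, 10.0]
        assert any("unsorted" in r.message for r in caplog.records)

    def test_negative_k_rejected(self, default_panel, default_incidence):
        with pytest.raises(ValueError):
            ridge_fit(default_panel, default_incidence, k=-1.0)


class TestSVR:
    def test_linear_response_fits_nearly_perfectly(self, default_panel, linear_lag0_incidence):
        res = KernelSVRModel(default_panel, linear_lag0_incidence, epsilon=1e-3).select()
        assert res.r2 > 0.99

    def test_rbf_beats_linear_on_radial_pattern(self, default_panel):
        """A bump in (lag0, lag4) space is captured by RBF, not a hyperplane."""
        x0 = (default_panel["lag0"] - default_panel["lag0"].mean()) / default_panel["lag0"].std()
        x4 = (default_panel["lag4"] - default_panel["lag4"].mean()) / default_panel["lag4"].std()
        inc = make_incidence(default_panel, 30.0 + 20.0 * np.exp(-(x0**2 + x4**2)))
        model = KernelSVRModel(default_panel, inc)
        assert model.fit("rbf").mse < model.fit("linear").mse

    def test_r2_mse_variance_identity(self, default_panel, default_incidence):
        res = svr_select(default_panel, default_incidence)
        var = np.var(res.observed)  # population variance, matching R² = 1 − SSE/SST
        assert res.r2 == pytest.approx(1.0 - res.mse / var, abs=1e-10)

    def test_selection_reports_all_kernels(self, default_panel, default_incidence):
        res = svr_select(default_panel, default_incidence)
        assert set(res.kernel_comparison["kernel"]) == {"linear", "sigmoid", "rbf", "poly"}
        assert res.mse == res.kernel_comparison["mse"].min()

    def test_degenerate_response_rejected(self, default_panel):
        inc = make_incidence(default_panel, np.full(len(default_panel), 40.0))
        with pytest.raises(ValueError, match="zero variance"):
            svr_select(default_panel, inc)


class TestPermutationImportance:
    def test_single_informative_lag_ranks_first(self, default_panel):
        inc = make_incidence(default_panel, 5.0 + 2.0 * default_panel["lag4"])
        model = KernelSVRModel(default_panel, inc)
        res = model.fit("rbf")
        imp = model.permutation_importance(res, n_repeats=10, seed=0)
        assert imp.idxmax() == "lag4"

    def test_constant_column_scores_exactly_zero(self, default_panel):
        panel = default_panel.copy()
        panel["lag7"] = 55.0  # permuting identical values changes nothing
        inc = make_incidence(panel, 5.0 + 2.0 * panel["lag4"])
        model = KernelSVRModel(panel, inc)
        res = model.fit("rbf")
        imp = model.permutation_importance(res, n_repeats=5, seed=0)
        assert imp["lag7"] == 0.0

    def test_deterministic_given_seed(self, default_panel, default_incidence):
        model = KernelSVRModel(default_panel, default_incidence)
        res = model.fit("rbf")
        a = model.permutation_importance(res, n_repeats=5, seed=3)
        b = model.permutation_importance(res, n_repeats=5, seed=3)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_ordering_matches_leave_one_out_refit_oracle(self, default_panel):
        """Two additive effects of different size: permutation ordering agrees
        with the loss increase from refitting without each feature."""
        inc = make_incidence(
            default_panel, 10.0 + 3.0 * default_panel["lag2"] + 0.5 * default_panel["lag8"]
        )
        model = KernelSVRModel(default_panel, inc, epsilon=1e-3)
        res = model.fit("linear")
        imp = model.permutation_importance(res, n_repeats=20, seed=0)

        from sklearn.svm import SVR

        lofo = {}
        for drop in ("lag2", "lag8"):
            cols = [j for j, c in enumerate(LAG_COLUMNS) if c != drop]
            est = SVR(kernel="linear", C=1.0, epsilon=1e-3)
            est.fit(model.Xs[:, cols], model.ys)
            resid = model.ys - est.predict(model.Xs[:, cols])
            lofo[drop] = float(np.mean(resid**2))
        assert (imp["lag2"] > imp["lag8"]) == (lofo["lag2"] > lofo["lag8"])

    def test_invalid_repeats_rejected(self, default_panel, default_incidence):
        model = KernelSVRModel(default_panel, default_incidence)
        res = model.fit("rbf")
        with pytest.raises(ValueError):
            model.permutation_importance(res, n_repeats=0)


class TestNetwork:
    def test_singleton_grid_selects_that_width(self, default_panel, default_incidence):
        res = network_fit(default_panel, default_incidence, node_grid=(7,), seed=0)
        assert res.selected_nodes == 7

    def test_deterministic_given_seed_and_config(self, default_panel, default_incidence):
        a = network_fit(default_panel, default_incidence, node_grid=(5, 8), seed=4)
        b = network_fit(default_panel, default_incidence, node_grid=(5, 8), seed=4)
        assert a.selected_nodes == b.selected_nodes
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_linear_response_fits_most_rows_within_5pct(
        self, default_panel, linear_lag0_incidence
    ):
        res = network_fit(default_panel, linear_lag0_incidence, node_grid=(7, 10), seed=0)
        rel = np.abs(res.observed - res.predictions) / np.abs(res.observed)
        assert (rel < 0.05).mean() >= 0.9

    def test_selected_width_minimizes_validation_mse(self, default_panel, default_incidence):
        res = network_fit(default_panel, default_incidence, node_grid=(5, 7, 9), seed=1)
        finite = res.validation_mse.dropna()
        assert res.validation_mse[res.selected_nodes] == finite.min()

    def test_invalid_training_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkTrainingConfig(holdout_fraction=1.5)


def test_all_models_share_one_metric_implementation(default_panel, default_incidence):
    """Every Results object's MetricSet is reproduced exactly by the shared
    evaluation routine on its own prediction series."""
    from lagrisk import metrics

    fits = [
        ridge_fit(default_panel, default_incidence, k=10.0),
        svr_select(default_panel, default_incidence),
        network_fit(default_panel, default_incidence, node_grid=(7,), seed=0),
    ]
    for res in fits:
        again = metrics(res.observed, res.predictions)
        assert res.metric_set == again


def test_feature_importance_functional_wrapper(default_panel, default_incidence):
    res = svr_select(default_panel, default_incidence)
    imp = feature_importance(res, default_panel, default_incidence, n_repeats=3, seed=0)
    assert list(imp.index) == LAG_COLUMNS
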