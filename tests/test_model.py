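import numpy as np
import pytest
from sklearn.base import clone
from sklearn.model_selection import GridSearchCV

from irbfnn import (
    IncrementalRBFRegressor,
    SimulationSpec,
    evaluate_grid,
    fit_incremental,
    fit_linear,
    minmax_apply,
    minmax_fit,
    minmax_invert,
    rmse,
    simulate_ee_dataset,
    simulate_piecewise_nonlinear,
)

from oracles import loop_rmse, normal_equations_lstsq


class TestMinMax:
    def test_maps_training_columns_onto_unit_interval(self):
        scaler = minmax_fit(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(minmax_apply(scaler, [2.0, 4.0, 6.0]),
                                   [0.0, 0.5, 1.0])

    def test_round_trip_identity(self, rng):
        X = rng.normal(size=(30, 3)) * 50 + 7
        scaler = minmax_fit(X)
        np.testing.assert_allclose(minmax_invert(scaler, minmax_apply(scaler, X)),
                                   X, atol=1e-12)

    def test_out_of_range_values_extend_affinely(self):
        scaler = minmax_fit(np.array([0.0, 10.0]))
        assert minmax_apply(scaler, np.array([-5.0]))[0] == pytest.approx(-0.5)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_fit(np.column_stack([np.arange(5.0), np.full(5, 3.0)]))


class TestLinearBackbone:
    def test_exact_line_recovered(self):
        X = np.array([[1.0], [2.0], [3.0]])
        lm = fit_linear(X, np.array([2.0, 4.0, 6.0]))
        assert lm.coefficients[0] == pytest.approx(2.0)
        assert lm.intercept == pytest.approx(0.0, abs=1e-12)

    def test_residuals_zero_mean_and_oracle_match(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        lm = fit_linear(X, y)
        resid = y - lm.predict(X)
        assert abs(resid.mean()) < 1e-9
        beta = normal_equations_lstsq(np.column_stack([np.ones(40), X]), y)
        assert lm.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(lm.coefficients, beta[1:], atol=1e-8)

    def test_rank_deficient_design_raises(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear(X, rng.normal(size=20))

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="samples"):
            fit_linear(np.zeros((3, 2)) + np.eye(3, 2), np.zeros(3))


class TestRmse:
    def test_known_values_and_oracle(self, rng):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        y, yh = rng.normal(size=50), rng.normal(size=50)
        assert rmse(y, yh) == pytest.approx(loop_rmse(y, yh), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            rmse([], [])
        with pytest.raises(ValueError, match="length"):
            rmse([1.0], [1.0, 2.0])


class TestIncrementalFit:
    def test_hidden_layer_size_is_c_times_p(self, ee_dataset):
        est = IncrementalRBFRegressor(n_contexts=4, n_clusters=2,
                                      random_state=0).fit(ee_dataset.X, ee_dataset.y)
        assert est.n_hidden_ == 8
        assert est.layer_.centers.shape == (8, 2)

    def test_purely_linear_data_gives_negligible_correction(self, rng):
        X = rng.uniform(0, 1, size=(80, 2))
        y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        est = IncrementalRBFRegressor(3, 2, random_state=1).fit(X, y)
        np.testing.assert_allclose(est.predict(X), est.predict_linear(X),
                                   atol=1e-6)

    def test_training_rmse_never_exceeds_linear_backbone(self, ee_dataset):
        for c in (1, 2, 4):
            est = IncrementalRBFRegressor(3, c, random_state=3).fit(
                ee_dataset.X, ee_dataset.y)
            assert est.train_rmse_ <= est.train_rmse_linear_ + 1e-12

    def test_predict_on_train_reproduces_fitted_values(self, ee_dataset):
        est = IncrementalRBFRegressor(3, 3, random_state=5).fit(
            ee_dataset.X, ee_dataset.y)
        np.testing.assert_allclose(est.predict(ee_dataset.X),
                                   est.fitted_values_, atol=1e-10)

    def test_zeroed_rbf_weights_reduce_to_linear(self, ee_dataset):
        est = IncrementalRBFRegressor(3, 3, random_state=5).fit(
            ee_dataset.X, ee_dataset.y)
        est.layer_.weights = np.zeros_like(est.layer_.weights)
        np.testing.assert_allclose(est.predict(ee_dataset.X),
                                   est.predict_linear(ee_dataset.X), atol=1e-12)

    def test_feature_shift_invariance(self, ee_dataset):
        """Min-max scaling absorbs affine shifts of a feature column, so
        shifting HR by a constant and refitting changes nothing."""
        est = IncrementalRBFRegressor(3, 3, random_state=2).fit(
            ee_dataset.X, ee_dataset.y)
        X_shift = ee_dataset.X.copy()
        X_shift[:, 0] += 250.0
        est2 = IncrementalRBFRegressor(3, 3, random_state=2).fit(
            X_shift, ee_dataset.y)
        Xq = ee_dataset.X[:25]
        Xq_shift = Xq.copy()
        Xq_shift[:, 0] += 250.0
        np.testing.assert_allclose(est2.predict(Xq_shift), est.predict(Xq),
                                   atol=1e-8)

    def test_underpopulated_context_error_names_the_context(self, rng):
        X = rng.uniform(0, 1, size=(60, 2))
        y = 1 + 2 * X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.05, 60)
        y[0] += 50.0  # one extreme residual isolates the top context
        with pytest.raises(ValueError, match="context 3"):
            IncrementalRBFRegressor(3, 3, random_state=0).fit(X, y)

    def test_feature_count_mismatch_on_predict(self, ee_dataset):
        est = IncrementalRBFRegressor(3, 2, random_state=0).fit(
            ee_dataset.X, ee_dataset.y)
        with pytest.raises(ValueError, match="features"):
            est.predict(np.zeros((4, 5)))

    def test_parameter_validation(self, ee_dataset):
        X, y = ee_dataset.X, ee_dataset.y
        with pytest.raises(ValueError):
            IncrementalRBFRegressor(n_contexts=1).fit(X, y)
        with pytest.raises(ValueError):
            IncrementalRBFRegressor(n_clusters=0).fit(X, y)
        with pytest.raises(ValueError):
            IncrementalRBFRegressor(m=1.0).fit(X, y)

    def test_normalize_target_flag(self, ee_dataset):
        est = IncrementalRBFRegressor(3, 2, normalize_target=False,
                                      random_state=4).fit(ee_dataset.X, ee_dataset.y)
        assert est.target_scaler_ is None
        assert est.train_rmse_ <= est.train_rmse_linear_ + 1e-12

    def test_functional_wrapper_matches_estimator(self, ee_dataset):
        from irbfnn import CFCMConfig, predict as predict_fn

        est = fit_incremental(ee_dataset.X, ee_dataset.y, p=3, c=2,
                              config=CFCMConfig(seed=11))
        direct = IncrementalRBFRegressor(3, 2, random_state=11).fit(
            ee_dataset.X, ee_dataset.y)
        np.testing.assert_array_equal(predict_fn(est, ee_dataset.X),
                                      direct.predict(ee_dataset.X))


class TestCapacityAndRecovery:
    def test_large_capacity_beats_single_cluster_on_noiseless_bumps(self):
        ds = simulate_ee_dataset(SimulationSpec(n=252, noise_sd=0.0, seed=42))
        fits = {c: IncrementalRBFRegressor(3, c, random_state=42).fit(ds.X, ds.y)
                for c in (1, 6)}
        for est in fits.values():
            assert est.train_rmse_ <= est.train_rmse_linear_ + 1e-12
        assert fits[6].train_rmse_ < fits[1].train_rmse_

    def test_piecewise_benchmark_halves_linear_training_error(self):
        ds = simulate_piecewise_nonlinear(500, seed=42)
        est = IncrementalRBFRegressor(3, 3, random_state=42).fit(ds.X, ds.y)
        assert est.train_rmse_ < 0.5 * est.train_rmse_linear_


class TestEvaluateGrid:
    def test_seeded_determinism_bitwise(self, ee_dataset):
        a = evaluate_grid(ee_dataset.X, ee_dataset.y, range(3, 4), range(2, 4),
                          n_repeats=2, seed=5)
        b = evaluate_grid(ee_dataset.X, ee_dataset.y, range(3, 4), range(2, 4),
                          n_repeats=2, seed=5)
        for pc in a.cells:
            assert a.cells[pc].train_rmses == b.cells[pc].train_rmses
            assert a.cells[pc].test_rmses == b.cells[pc].test_rmses

    def test_per_repeat_lists_have_length_n_repeats(self, ee_dataset):
        rep = evaluate_grid(ee_dataset.X, ee_dataset.y, range(3, 5), range(2, 4),
                            n_repeats=3, seed=1)
        for cell in rep.cells.values():
            assert len(cell.train_rmses) == 3
            assert len(cell.test_rmses) == 3

    def test_failed_cells_recorded_not_skipped(self, rng):
        X = rng.uniform(0, 1, size=(60, 2))
        y = 1 + 2 * X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.05, 60)
        y[0] += 50.0
        rep = evaluate_grid(X, y, range(3, 4), range(2, 4), n_repeats=2, seed=0)
        df = rep.to_frame()
        assert df.n_failed.sum() > 0
        assert set(df.columns) == {"p", "c", "mean_train_rmse",
                                   "mean_test_rmse", "n_failed"}
        failed = [c for cell in rep.cells.values() for c in cell.failures]
        assert all("context" in msg for msg in failed)

    def test_split_smaller_than_largest_layer_raises(self, rng):
        X = rng.uniform(size=(30, 2))
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="smaller than the largest"):
            evaluate_grid(X, y, range(5, 7), range(5, 7), n_repeats=1, seed=0)

    def test_best_cell_beats_linear_on_same_splits(self, ee_dataset):
        """The grid winner should improve on the plain linear backbone
        evaluated with identical repeated splits."""
        from sklearn.model_selection import ShuffleSplit

        rep = evaluate_grid(ee_dataset.X, ee_dataset.y, range(3, 5),
                            range(2, 4), n_repeats=4, seed=42)
        best_rmse = rep.cells[rep.best].mean_test_rmse
        rng_local = np.random.default_rng(42)
        split_seed = int(rng_local.integers(2**31))
        splitter = ShuffleSplit(n_splits=4, train_size=0.6,
                                random_state=split_seed)
        lr_rmses = []
        for tr, te in splitter.split(ee_dataset.X):
            lm = fit_linear(ee_dataset.X[tr], ee_dataset.y[tr])
            lr_rmses.append(rmse(ee_dataset.y[te], lm.predict(ee_dataset.X[te])))
        assert best_rmse <= np.mean(lr_rmses)


class TestSklearnIntegration:
    def test_clone_and_params_round_trip(self):
        est = IncrementalRBFRegressor(4, 2, m=1.8, ridge=1e-8, random_state=9)
        params = est.get_params()
        assert params["n_contexts"] == 4 and params["ridge"] == 1e-8
        est2 = clone(est).set_params(n_clusters=5)
        assert est2.get_params()["n_clusters"] == 5
        assert est.get_params()["n_clusters"] == 2

    def test_grid_search_cv_smoke(self, ee_dataset):
        gs = GridSearchCV(
            IncrementalRBFRegressor(random_state=0),
            {"n_clusters": [2, 3]},
            cv=3,
            scoring="neg_root_mean_squared_error",
        )
        gs.fit(ee_dataset.X, ee_dataset.y)
        assert gs.best_params_["n_clusters"] in (2, 3)
        assert -gs.best_score_ < rmse(ee_dataset.y,
                                      fit_linear(ee_dataset.X, ee_dataset.y)
                                      .predict(ee_dataset.X)) * 2
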