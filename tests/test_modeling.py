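import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frostfield import modeling
from frostfield.modeling import (
    ALGORITHMS,
    SOURCES,
    SOURCE_FEATURES,
    evaluate,
    fit_mlr,
    fit_nn,
    fit_svm,
    run_cells,
    stratified_split,
)
from frostfield.selection import select_features


class TestStratifiedSplit:
    @pytest.mark.parametrize("n, n_train", [(10, 7), (160, 112), (209, 146), (49, 34)])
    def test_train_totals_follow_the_7_3_ratio(self, n, n_train):
        fdi = np.random.default_rng(1).uniform(0, 1, n)
        split = stratified_split(fdi, ratio=0.7, seed=0)
        assert (split["role"] == "train").sum() == n_train
        assert (split["role"] == "test").sum() == n - n_train

    def test_seeded_determinism_and_seed_sensitivity(self):
        fdi = np.random.default_rng(2).uniform(0, 1, 60)
        a = stratified_split(fdi, seed=5)
        b = stratified_split(fdi, seed=5)
        c = stratified_split(fdi, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a["role"].equals(c["role"])
        assert (c["role"] == "train").sum() == (a["role"] == "train").sum()

    def test_stratum_proportions_within_one_plot(self):
        fdi = np.random.default_rng(3).uniform(0, 1, 83)
        split = stratified_split(fdi, ratio=0.7, n_strata=5, seed=1)
        for _, sub in split.groupby("stratum"):
            n_train = (sub["role"] == "train").sum()
            assert abs(n_train - 0.7 * len(sub)) <= 1.0

    def test_partition_is_disjoint_and_complete(self):
        fdi = np.random.default_rng(4).uniform(0, 1, 31)
        split = stratified_split(fdi, seed=0)
        assert set(split["role"]) == {"train", "test"}
        assert len(split) == 31

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0.1, 0.9]))


class TestMLR:
    def test_planted_coefficients_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (50, 2))
        y = 0.1 + 0.5 * X[:, 0] - 0.2 * X[:, 1]
        model = fit_mlr(X, y)
        assert model.intercept == pytest.approx(0.1, abs=1e-8)
        np.testing.assert_allclose(model.coef, [0.5, -0.2], atol=1e-8)

    def test_two_points_interpolated_exactly(self):
        model = fit_mlr(np.array([[0.0], [1.0]]), np.array([1.0, 3.0]))
        np.testing.assert_allclose(
            model.predict(np.array([[0.0], [1.0]])), [1.0, 3.0], atol=1e-12
        )

    def test_constant_response_gives_flat_model(self):
        X = np.random.default_rng(1).normal(size=(20, 3))
        model = fit_mlr(X, np.full(20, 0.4))
        assert model.intercept == pytest.approx(0.4, abs=1e-10)
        np.testing.assert_allclose(model.coef, 0.0, atol=1e-10)

    def test_rank_deficient_design_warns_and_returns_min_norm(self, caplog):
        X = np.ones((10, 2))
        X[:, 1] = X[:, 0]  # duplicated column
        with caplog.at_level("WARNING", logger="frostfield.modeling"):
            model = fit_mlr(X, np.random.default_rng(2).normal(size=10))
        assert "rank deficient" in caplog.text
        assert np.isfinite(model.coef).all()


class TestSVM:
    def test_tube_dominance_gives_flat_predictor(self):
        """epsilon wider than the response spread: w = 0, all residuals
        inside the tube, and duplication leaves the optimum unchanged."""
        X = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
        y = np.array([0.50, 0.51, 0.49, 0.50, 0.52])
        model = fit_svm(X, y, C=0.19, epsilon=0.2)
        pred = model.predict(X)
        assert np.ptp(pred) < 1e-6                      # flat
        assert np.abs(pred - y).max() <= 0.2 + 1e-6     # inside the tube
        doubled = fit_svm(np.vstack([X, X]), np.concatenate([y, y]),
                          C=0.19, epsilon=0.2)
        np.testing.assert_allclose(doubled.predict(X), pred, atol=1e-6)

    def test_noiseless_linear_signal_recovered(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (40, 1))
        y = 0.3 + 0.5 * X[:, 0]
        model = fit_svm(X, y, C=100.0, epsilon=1e-4)
        grid = np.array([[0.2], [0.8]])
        slope = np.diff(model.predict(grid))[0] / 0.6
        assert slope == pytest.approx(0.5, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            fit_svm(np.zeros((5, 1)), np.zeros(5), C=0.0)


class TestNN:
    def test_noiseless_linear_signal_high_r2(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (80, 3))
        beta = np.array([0.4, -0.3, 0.2])
        y = 0.5 + X @ beta
        model = fit_nn(X[:60], y[:60], seed=0)
        metrics = evaluate(y[60:], model.predict(X[60:]))
        assert metrics.r2 >= 0.99

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (40, 2))
        y = rng.uniform(0, 1, 40)
        a = fit_nn(X, y, seed=11).predict(X)
        b = fit_nn(X, y, seed=11).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_pure_noise_not_significantly_positive(self):
        """No-signal control: test R^2 centers at/below zero over 20 seeds."""
        rng = np.random.default_rng(6)
        r2 = []
        for seed in range(20):
            X = rng.uniform(-1, 1, (60, 3))
            y = rng.normal(size=60)
            model = fit_nn(X[:42], y[:42], seed=seed)
            r2.append(evaluate(y[42:], model.predict(X[42:])).r2)
        r2 = np.array(r2)
        t = r2.mean() / (r2.std(ddof=1) / np.sqrt(len(r2)))
        assert t < stats.t.ppf(0.99, len(r2) - 1)


class TestEvaluate:
    def test_perfect_and_null_predictions(self):
        y = np.array([0.2, 0.5, 0.8])
        perfect = evaluate(y, y)
        assert (perfect.r2, perfect.rmse, perfect.mae) == (1.0, 0.0, 0.0)
        null = evaluate(y, np.full(3, y.mean()))
        assert null.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_metrics(self):
        m = evaluate([0.2, 0.4, 0.6], [0.3, 0.4, 0.5])
        assert m.rmse == pytest.approx(np.sqrt(0.02 / 3))
        assert m.mae == pytest.approx(0.2 / 3)
        assert m.r2 == pytest.approx(0.75)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=50)
        yhat = y + rng.normal(size=50)
        m = evaluate(y, yhat)
        assert m.rmse >= m.mae >= 0.0

    def test_zero_variance_truth_flags_r2(self):
        m = evaluate([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
        assert np.isnan(m.r2)
        assert m.rmse > 0


@pytest.fixture(scope="module")
def cells(noisy_table):
    report = select_features(noisy_table)
    reports, skipped = run_cells(
        noisy_table, report, split_seed=1, nn_seed=1,
        nn_params={"max_iter": 60},
    )
    return reports, skipped


class TestRunCells:
    def test_full_grid_has_27_cells(self, cells):
        reports, skipped = cells
        skipped_cells = sum(
            1 if "algorithm" in s else 3 if "source" in s else 9
            for s in skipped
        )
        assert len(reports) + skipped_cells == len(SOURCES) * len(ALGORITHMS) * 3
        seen = {(r.group, r.source, r.algorithm) for r in reports}
        assert len(seen) == len(reports)

    def test_multisource_features_are_the_union(self, cells):
        reports, _ = cells
        by_cell = {(r.group, r.source): set(r.features) for r in reports}
        for group in ("ALL", "GREEN", "RED"):
            rgb = by_cell.get((group, "RGB"), set())
            msi = by_cell.get((group, "MSI"), set())
            multi = by_cell.get((group, "MULTISOURCE"), set())
            if multi:
                assert multi == rgb | msi
                assert len(multi) == len(rgb) + len(msi)

    def test_predictions_cover_every_plot_once(self, cells, noisy_table):
        reports, _ = cells
        rep = reports[0]
        assert sorted(rep.predictions["plot_id"]) == sorted(noisy_table["plot_id"])
        n_group = len(noisy_table) if rep.group == "ALL" else (
            noisy_table["cultivar_color"].str.upper() == rep.group
        ).sum()
        assert rep.train.n + rep.test.n == n_group

    def test_empty_selection_skips_cells_with_reason(self, noisy_table):
        report = select_features(noisy_table)
        report = report.assign(selected=False)
        reports, skipped = run_cells(noisy_table, report)
        assert not reports
        assert all(s["reason"] == "no selected feature" for s in skipped)

    def test_feature_sources_are_disjoint(self):
        assert not set(SOURCE_FEATURES["RGB"]) & set(SOURCE_FEATURES["MSI"])
        assert len(SOURCE_FEATURES["MULTISOURCE"]) == 70


def test_mlr_train_r2_dominates_other_linear_predictors(noisy_table):
    """Least squares maximizes train R^2 over all affine predictors, so the
    linear-kernel SVM can never beat MLR on the training split."""
    feats = ["R840", "R668", "ExG"]
    X = noisy_table[feats].to_numpy()
    y = noisy_table["fdi"].to_numpy()
    mlr = fit_mlr(X, y)
    svm = fit_svm(X, y)
    r2_mlr = evaluate(y, mlr.predict(X)).r2
    r2_svm = evaluate(y, svm.predict(X)).r2
    assert r2_mlr >= r2_svm - 1e-10
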