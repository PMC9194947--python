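"""The end-to-end SuffPCR estimator."""

import numpy as np
import pandas as pd
import pytest

from suffpcr.model import (
    SuffPCR,
    default_lambda_grid,
    fit_logistic,
    standardize,
    tune_lambda,
)
from suffpcr.simulate import FactorModelParams, generate, generate_splits


class TestStandardize:
    def test_already_standardized_unchanged(self, rng):
        n = 200
        X = rng.standard_normal((n, 4))
        X = (X - X.mean(0)) / X.std(0)
        Xs, _, _ = standardize(X)
        assert np.max(np.abs(Xs - X)) < 1e-12

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((30, 5))
        X[:, 2] = 7.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            Xs, _, params = standardize(X)
        assert Xs.shape[1] == 4
        assert np.array_equal(params.dropped, [2])

    def test_unit_diagonal_second_moment(self, rng):
        X = rng.standard_normal((40, 8)) * rng.uniform(0.1, 9, 8) + 3
        Xs, _, _ = standardize(X)
        S = Xs.T @ Xs / 40
        assert np.max(np.abs(np.diag(S) - 1.0)) < 1e-8

    def test_missing_values_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        X[4, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            standardize(X)


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        """With zero noise the support is found exactly and held-out
        predictions are essentially perfect."""
        params = FactorModelParams(n=60, p=80, d=3, r=4,
                                   snr_x=np.inf, snr_y=np.inf, seed=3)
        train, _, test = generate_splits(params)
        model = SuffPCR(train.y, train.X, d=3)
        # the p - s noiseless columns are identically zero and dropped
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = model.fit(0.01, max_iter=300)
        assert set(res.support.tolist()) == set(train.support.tolist())
        pred = res.predict(test.X)
        assert np.mean((pred - test.y) ** 2) < 1e-6

    def test_kill_regime_falls_back_to_intercept(self, small_factor_data):
        train, _, _ = small_factor_data
        model = SuffPCR(train.y, train.X, d=3)
        res = model.fit(1e6, max_iter=60)
        assert "empty_support" in res.flags
        assert res.n_selected == 0
        assert np.allclose(res.predict(train.X), train.y.mean())

    def test_beta_is_basis_times_gamma_on_support_only(self,
                                                       small_factor_data):
        train, _, _ = small_factor_data
        res = SuffPCR(train.y, train.X, d=3).fit(0.2, max_iter=150)
        beta = res.params
        assert np.allclose(beta[res.support],
                           (res.V_hat.V @ res.gamma)[res.V_hat.support])
        off = np.setdiff1d(np.arange(train.p), res.support)
        assert np.all(beta[off] == 0.0)
        # row-sparse basis implies sparse coefficients, by construction
        assert set(np.flatnonzero(beta)) <= set(res.support.tolist())


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        params = FactorModelParams(n=100, p=200, d=3, r=5, seed=7)
        train, val, test = generate_splits(params)
        res = SuffPCR(train.y, train.X, d=3).fit(0.2, max_iter=150)
        return train, test, res

    def test_matches_manual_dot_product(self, fitted, rng):
        train, test, res = fitted
        rows = rng.choice(test.n, 3, replace=False)
        for i in rows:
            x = test.X[i]
            xs = (x[res.model._std.kept] - res.model._std.feature_means) \
                / res.model._std.feature_scales
            manual = float(xs @ res.beta_std + res.intercept)
            assert res.predict(x[None, :])[0] == pytest.approx(manual,
                                                               abs=1e-10)

    def test_non_support_columns_do_not_matter(self, fitted, rng):
        train, test, res = fitted
        X2 = test.X.copy()
        off = np.setdiff1d(np.arange(test.p), res.support)
        X2[:, off] = X2[:, rng.permutation(off)]
        assert np.array_equal(res.predict(test.X), res.predict(X2))

    def test_missing_named_features_rejected(self, rng):
        X = rng.standard_normal((40, 12))
        names = [f"g{j}" for j in range(12)]
        y = X[:, 0] + rng.standard_normal(40)
        res = SuffPCR(y, X, d=2, feature_names=names).fit(0.3, max_iter=100)
        df = pd.DataFrame(X[:, :10], columns=names[:10])
        with pytest.raises(ValueError, match="missing"):
            res.predict(df)

    def test_named_features_joined_by_identifier(self, fitted, rng):
        train, test, res = fitted
        # no names on this model: arrays must have the training width
        with pytest.raises(ValueError, match="features"):
            res.predict(test.X[:, :-1])


class TestTuneLambda:
    def test_single_value_grid_returned(self, small_factor_data):
        train, val, _ = small_factor_data
        X = np.vstack([train.X, val.X])
        y = np.concatenate([train.y, val.y])
        best, path = tune_lambda(X, y, 3, [0.2], np.arange(train.n),
                                 np.arange(train.n, 2 * train.n),
                                 max_iter=100)
        assert best == 0.2
        assert len(path) == 1

    def test_duplicates_deduplicated(self, small_factor_data):
        train, val, _ = small_factor_data
        X = np.vstack([train.X, val.X])
        y = np.concatenate([train.y, val.y])
        best, path = tune_lambda(X, y, 3, [0.3, 0.3, 0.1],
                                 np.arange(train.n),
                                 np.arange(train.n, 2 * train.n),
                                 max_iter=100)
        assert [l for l, _, _ in path] == [0.3, 0.1]

    def test_selected_lambda_minimizes_validation_mse(self,
                                                      small_factor_data):
        train, val, _ = small_factor_data
        X = np.vstack([train.X, val.X])
        y = np.concatenate([train.y, val.y])
        grid = default_lambda_grid(train.n, train.p, num=4)
        best, path = tune_lambda(X, y, 3, grid, np.arange(train.n),
                                 np.arange(train.n, 2 * train.n),
                                 max_iter=100, selection="min")
        scores = {l: s for l, _, s in path}
        assert scores[best] == min(scores.values())

    def test_one_se_rule_prefers_sparser_model(self, small_factor_data):
        """The 1-SE rule never selects a smaller lambda than the plain
        minimizer."""
        train, val, _ = small_factor_data
        X = np.vstack([train.X, val.X])
        y = np.concatenate([train.y, val.y])
        grid = default_lambda_grid(train.n, train.p, num=4)
        tr = np.arange(train.n)
        va = np.arange(train.n, 2 * train.n)
        best_min, _ = tune_lambda(X, y, 3, grid, tr, va, max_iter=100,
                                  selection="min")
        best_1se, _ = tune_lambda(X, y, 3, grid, tr, va, max_iter=100,
                                  selection="1se")
        assert best_1se >= best_min

    def test_overlapping_splits_rejected(self, small_factor_data):
        train, _, _ = small_factor_data
        with pytest.raises(ValueError, match="overlap"):
            tune_lambda(train.X, train.y, 3, [0.1], [0, 1, 2], [2, 3])

    def test_empty_grid_rejected(self, small_factor_data):
        train, _, _ = small_factor_data
        with pytest.raises(ValueError, match="empty"):
            tune_lambda(train.X, train.y, 3, [], [0, 1], [2, 3])


class TestLogistic:
    def test_held_out_accuracy_on_thresholded_phenotype(self):
        """Labels from thresholding the Gaussian response at its median
        are classified well above chance."""
        params = FactorModelParams(n=100, p=200, d=3, r=5, seed=9)
        train, _, test = generate_splits(params)
        labels = (train.y > np.median(train.y)).astype(float)
        res = fit_logistic(train.X, labels, d=3, lam=0.2, max_iter=150)
        test_labels = (test.y > np.median(train.y)).astype(float)
        acc = np.mean((res.predict(test.X) > 0.5) == (test_labels > 0.5))
        assert acc > 0.8

    def test_one_class_rejected(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="class"):
            fit_logistic(X, np.ones(20), d=2, lam=0.1)

    def test_separation_flag_raised_for_ordered_scores(self, rng):
        """d = 1 with labels perfectly ordered along the dominant
        direction: the bounded-iteration logistic fit flags separation."""
        n, p = 60, 20
        u = np.sort(rng.standard_normal(n)) * 3
        v = np.zeros(p)
        v[:4] = 0.5
        X = np.outer(u, v) + 0.01 * rng.standard_normal((n, p))
        labels = (u > 0).astype(float)
        res = fit_logistic(X, labels, d=1, lam=0.05, max_iter=150)
        assert "separation" in res.flags

    def test_summary_mentions_family_and_selection(self, small_factor_data):
        train, _, _ = small_factor_data
        res = SuffPCR(train.y, train.X, d=3).fit(0.2, max_iter=100)
        text = res.summary()
        assert "gaussian" in text
        assert str(res.n_selected) in text


class TestModelValidation:
    def test_bad_family(self, rng):
        with pytest.raises(ValueError, match="family"):
            SuffPCR(rng.standard_normal(10),
                    rng.standard_normal((10, 5)), d=2, family="poisson")

    def test_d_out_of_range(self, rng):
        with pytest.raises(ValueError, match="d"):
            SuffPCR(rng.standard_normal(10),
                    rng.standard_normal((10, 5)), d=5)

    def test_from_dataframe_round_trip(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        df = pd.DataFrame(X, columns=[f"g{j}" for j in range(6)])
        df["pheno"] = y
        m = SuffPCR.from_dataframe(df, "pheno", d=2)
        assert m.p == 6
        assert m.feature_names == [f"g{j}" for j in range(6)]
        assert np.array_equal(m.endog, y)
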