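"""Model contracts: regularization behaviour, support constraints,
penalized-forest limits, determinism, tuning tie-breaks."""

import numpy as np
import pytest

from sbsl.metrics import auroc
from sbsl.models import (
    default_grid,
    fit_elastic_net,
    fit_l0l2,
    fit_l0l2_single,
    fit_muvr,
    fit_rrf,
    predict_score,
    tune,
)


class TestElasticNet:
    def test_full_shrinkage_leaves_log_odds_intercept(self, toy_classification):
        X, y = toy_classification
        m = fit_elastic_net(X, y, alpha=1.0, lam=100.0)
        assert np.allclose(m.params["coef"], 0.0)
        logodds = np.log(y.mean() / (1 - y.mean()))
        assert m.params["intercept"] == pytest.approx(logodds, abs=0.05)
        assert m.selected_features == []

    def test_sign_follows_separation(self, toy_classification):
        X, y = toy_classification
        m = fit_elastic_net(X, y, alpha=0.5, lam=1e-3)
        assert m.params["coef"][4] > 0  # the informative feature

    def test_single_class_rejected(self, toy_classification):
        X, _ = toy_classification
        with pytest.raises(ValueError):
            fit_elastic_net(X, np.ones(len(X), dtype=int))

    def test_determinism(self, toy_classification):
        X, y = toy_classification
        s1 = predict_score(fit_elastic_net(X, y, 0.5, 1e-3, seed=3), X)
        s2 = predict_score(fit_elastic_net(X, y, 0.5, 1e-3, seed=3), X)
        np.testing.assert_array_equal(s1, s2)


class TestL0L2:
    def test_support_size_never_exceeded(self, toy_classification):
        X, y = toy_classification
        for k in (1, 3, 5):
            coef, _ = fit_l0l2_single(X, y, k, 1e-3)
            assert np.count_nonzero(coef) <= k

    def test_k_zero_is_intercept_only(self, toy_classification):
        X, y = toy_classification
        coef, b0 = fit_l0l2_single(X, y, 0, 1e-2)
        assert np.count_nonzero(coef) == 0
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_k1_recovers_informative_feature(self, toy_classification):
        X, y = toy_classification
        coef, _ = fit_l0l2_single(X, y, 1, 1e-4)
        assert np.flatnonzero(coef).tolist() == [4]

    def test_oversized_support_rejected(self, toy_classification):
        X, y = toy_classification
        with pytest.raises(ValueError, match="exceeds"):
            fit_l0l2(X, y, support_grid=[X.shape[1] + 1], gamma_grid=[1e-3])

    def test_cv_selection_returns_valid_model(self, toy_classification):
        X, y = toy_classification
        m = fit_l0l2(X, y, support_grid=[1, 2, 4], gamma_grid=[1e-3],
                     cv_folds=4, cv_repeats=1)
        assert np.count_nonzero(m.params["coef"]) <= m.hyperparameters["k"]
        assert "f4" in m.selected_features


class TestRRF:
    def test_invalid_parameters(self, toy_classification):
        X, y = toy_classification
        with pytest.raises(ValueError):
            fit_rrf(X, y, mtry=4, coef_reg=0.0)
        with pytest.raises(ValueError):
            fit_rrf(X, y, mtry=X.shape[1] + 1, coef_reg=0.5)

    def test_determinism(self, toy_classification):
        X, y = toy_classification
        s1 = predict_score(fit_rrf(X, y, 4, 0.7, seed=11, n_trees=50), X)
        s2 = predict_score(fit_rrf(X, y, 4, 0.7, seed=11, n_trees=50), X)
        np.testing.assert_array_equal(s1, s2)

    def test_penalty_shrinks_used_feature_set_with_duplicates(self, toy_classification):
        X, y = toy_classification
        Xd = np.hstack([X, X])  # every feature duplicated
        used_plain, used_reg = [], []
        for seed in range(5):
            used_plain.append(len(fit_rrf(Xd, y, 6, 1.0, seed=seed, n_trees=30,
                                          min_leaf=30).selected_features))
            used_reg.append(len(fit_rrf(Xd, y, 6, 0.3, seed=seed, n_trees=30,
                                        min_leaf=30).selected_features))
        assert np.mean(used_reg) < np.mean(used_plain)

    def test_learns_signal(self, toy_classification):
        X, y = toy_classification
        m = fit_rrf(X[:300], y[:300], 4, 0.8, seed=0, n_trees=200)
        assert auroc(predict_score(m, X[300:]), y[300:]) > 0.8


class TestMUVR:
    def test_parameter_validation(self, toy_classification):
        X, y = toy_classification
        with pytest.raises(ValueError, match="terminate"):
            fit_muvr(X, y, var_ratio=1.0)
        with pytest.raises(ValueError, match="folds"):
            fit_muvr(X[:8], y[:8], n_outer=10)

    def test_paper_default_schedule_accepted_and_recovers_signal(self, toy_classification):
        X, y = toy_classification
        m = fit_muvr(X, y, n_rep=2, n_outer=5, var_ratio=0.8, seed=0,
                     inner_trees=30, final_trees=60)
        assert "f4" in m.selected_features
        assert 1 <= m.meta["n_opt_mid"] <= X.shape[1]

    def test_selected_features_subset_of_training_features(self, toy_classification):
        X, y = toy_classification
        m = fit_muvr(X, y, n_rep=1, n_outer=4, var_ratio=0.7, seed=1,
                     inner_trees=20, final_trees=40)
        assert set(m.selected_features) <= set(m.feature_names)


class TestPredictScore:
    def test_intercept_only_constant(self, toy_classification):
        X, y = toy_classification
        m = fit_elastic_net(X, y, 1.0, 100.0)
        s = predict_score(m, X)
        assert np.allclose(s, s[0])
        assert ((s >= 0) & (s <= 1)).all()

    def test_column_mismatch_rejected(self, toy_classification):
        X, y = toy_classification
        m = fit_elastic_net(X, y, 0.5, 1e-3)
        with pytest.raises(ValueError):
            predict_score(m, X[:, :5])


class TestTune:
    def test_single_point_grid(self, toy_classification):
        X, y = toy_classification
        spec = tune("elastic_net", X, y, grid=[{"alpha": 0.5, "lam": 1e-3}],
                    folds=3, repeats=1)
        assert spec["alpha"] == 0.5 and spec["lam"] == 1e-3

    def test_empty_grid_rejected(self, toy_classification):
        X, y = toy_classification
        with pytest.raises(ValueError, match="empty"):
            tune("elastic_net", X, y, grid=[])

    def test_noise_data_prefers_strong_regularization(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(400, 8))
            y = rng.integers(0, 2, 400)
            spec = tune("elastic_net", X, y,
                        grid=[{"alpha": 1.0, "lam": l} for l in (1e-4, 1e-2, 1.0)],
                        seed=seed, folds=10, repeats=2)
            if spec["lam"] == 1.0:
                hits += 1
        assert hits >= 8

    def test_default_grids_cover_declared_spaces(self):
        for pt in default_grid("elastic_net"):
            assert 0 <= pt["alpha"] <= 1 and 0 <= pt["lam"] <= 1
        for pt in default_grid("rrf"):
            assert pt["mtry"] in (4, 8) and 0.5 <= pt["coef_reg"] <= 1
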