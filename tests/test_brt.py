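"""Boosting engine: deviance descent, influence, projection, serialization."""

import numpy as np
import pytest

from conftest import make_stack
from sdmshift.brt import (BRTConfig, BRTModel, bernoulli_deviance, fit_brt,
                          predict_map, relative_influence, select_n_trees)
from sdmshift.evaluate import auc
from sdmshift.grid import Grid


def _sigmoid(z):
    return 1 / (1 + np.exp(-z))


class TestFitBasics:
    def test_prediction_near_intercept_for_tiny_lr(self, rng):
        X = rng.normal(size=(50, 2))
        y = (rng.random(50) < 0.3).astype(float)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        m = fit_brt(X, y, BRTConfig(learning_rate=1e-6, max_trees=1, step=1, seed=0))
        np.testing.assert_allclose(m.predict(X), y.mean(), atol=1e-4)

    def test_separable_1d_reaches_training_auc_one(self, rng):
        x = np.concatenate([rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1.0, 30)])
        y = np.concatenate([np.zeros(30), np.ones(30)])
        m = fit_brt(x[:, None], y, BRTConfig(learning_rate=0.1, tree_complexity=1,
                                             max_trees=50, step=10, seed=1))
        s = m.predict(x[:, None])
        assert auc(s[y == 1], s[y == 0]) == 1.0

    def test_pure_noise_heldout_auc_near_half(self, rng):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 3))
            y = r.permutation(np.concatenate([np.ones(100), np.zeros(100)]))
            m = fit_brt(X[:150], y[:150],
                        BRTConfig(learning_rate=0.05, max_trees=50, step=10, seed=seed))
            s = m.predict(X[150:])
            yt = y[150:]
            aucs.append(auc(s[yt == 1], s[yt == 0]))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_rejects_bad_labels_and_single_class(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="labels"):
            fit_brt(X, np.full(10, 2.0))
        with pytest.raises(ValueError, match="presence"):
            fit_brt(X, np.ones(10))

    def test_train_deviance_nonincreasing_without_bagging(self, rng):
        X = rng.normal(size=(120, 3))
        logit = 1.5 * X[:, 0] - X[:, 1]
        y = (rng.random(120) < _sigmoid(logit)).astype(float)
        cfg = BRTConfig(learning_rate=0.05, bag_fraction=1.0, max_trees=60,
                        step=10, seed=2)
        m = fit_brt(X, y, cfg)
        devs = [bernoulli_deviance(y, _sigmoid(F)) for _, F in m.staged_decision(X)]
        assert all(b <= a + 1e-12 for a, b in zip(devs, devs[1:]))

    def test_fixed_seed_bit_reproducible(self, rng):
        X = rng.normal(size=(80, 3))
        y = np.concatenate([np.ones(40), np.zeros(40)])
        cfg = BRTConfig(learning_rate=0.05, max_trees=30, step=10, seed=5)
        p1 = fit_brt(X, y, cfg).predict(X)
        p2 = fit_brt(X, y, cfg).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestInfluence:
    def test_sums_to_100_and_single_split_is_total(self, rng):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        m = fit_brt(x[:, None], y, BRTConfig(learning_rate=0.1, tree_complexity=1,
                                             max_trees=1, step=1, seed=0))
        infl = relative_influence(m)
        assert infl["x0"] == pytest.approx(100.0, abs=1e-6)

    def test_informative_predictor_dominates_noise(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 4))
            y = (r.random(200) < _sigmoid(2.0 * X[:, 0])).astype(float)
            m = fit_brt(X, y, BRTConfig(learning_rate=0.05, max_trees=80,
                                        step=10, seed=seed))
            infl = relative_influence(m)
            wins += infl["x0"] > max(infl["x1"], infl["x2"], infl["x3"])
        assert wins >= 18

    def test_sum_invariant_for_any_model(self, rng):
        X = rng.normal(size=(60, 5))
        y = np.concatenate([np.ones(30), np.zeros(30)])
        m = fit_brt(X, y, BRTConfig(learning_rate=0.05, max_trees=40, step=10, seed=3))
        assert sum(relative_influence(m).values()) == pytest.approx(100.0, abs=1e-6)


class TestCategorical:
    def test_categorical_split_fits_group_means(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=300).astype(float)
        y = (rng.random(300) < np.where(codes == 1.0, 0.9, 0.1)).astype(float)
        m = fit_brt(codes[:, None], y,
                    BRTConfig(learning_rate=0.1, tree_complexity=1, max_trees=60,
                              step=10, seed=1), categorical=[0])
        p = m.predict(np.array([[0.0], [1.0], [2.0]]))
        assert p[1] > 0.7 and p[0] < 0.3 and p[2] < 0.3

    def test_unseen_category_routes_to_populous_child(self):
        rng = np.random.default_rng(1)
        codes = np.concatenate([np.zeros(80), np.ones(20)])
        y = np.concatenate([np.ones(80) * 0, np.ones(20)])
        y[:5] = 1  # keep both classes in the majority code
        m = fit_brt(codes[:, None], y,
                    BRTConfig(learning_rate=0.1, tree_complexity=1, max_trees=30,
                              step=10, seed=2), categorical=[0])
        p_unseen = m.predict(np.array([[7.0]]))[0]
        p_majority = m.predict(np.array([[0.0]]))[0]
        assert p_unseen == pytest.approx(p_majority, abs=1e-12)


class TestSelectNTrees:
    def _signal(self, n=200, seed=0):
        r = np.random.default_rng(seed)
        X = r.normal(size=(n, 3))
        y = (r.random(n) < _sigmoid(2.5 * X[:, 0])).astype(float)
        return X, y

    def test_still_decreasing_returns_max_trees(self):
        X, y = self._signal()
        cfg = BRTConfig(learning_rate=0.001, max_trees=60, step=20, cv_folds=4, seed=0)
        n_opt, curve = select_n_trees(X, y, cfg)
        assert n_opt == 60
        devs = [d for _, d in curve]
        assert devs[-1] == min(devs)

    def test_interior_minimum_found_with_overfitting_lr(self):
        # large lr overfits quickly: held-out deviance is U-shaped
        X, y = self._signal(n=80, seed=3)
        cfg = BRTConfig(learning_rate=1.0, bag_fraction=1.0, max_trees=300,
                        step=10, cv_folds=4, seed=3)
        n_opt, curve = select_n_trees(X, y, cfg)
        assert n_opt < 300

    def test_tie_takes_smaller_count(self):
        # constant features: every checkpoint has identical deviance
        X = np.zeros((40, 2))
        y = np.concatenate([np.ones(20), np.zeros(20)])
        cfg = BRTConfig(learning_rate=0.1, bag_fraction=1.0, max_trees=40,
                        step=10, cv_folds=4, seed=1)
        n_opt, curve = select_n_trees(X, y, cfg)
        assert n_opt == curve[0][0]


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, tmp_path, rng):
        X = rng.normal(size=(80, 3))
        y = np.concatenate([np.ones(40), np.zeros(40)])
        m = fit_brt(X, y, BRTConfig(learning_rate=0.05, max_trees=25, step=5, seed=7),
                    categorical=[2], feature_names=["a", "b", "g"])
        path = m.save(tmp_path / "m.json")
        m2 = BRTModel.load(path)
        np.testing.assert_array_equal(m.predict(X), m2.predict(X))
        assert m2.feature_names == ["a", "b", "g"]


class TestPredictMap:
    def test_zero_trees_constant_at_inverse_logit_intercept(self, rng):
        grid = Grid(3, 3, 0, 0, 1.0)
        stack = make_stack(grid, {"a": rng.normal(size=(3, 3))})
        X = rng.normal(size=(30, 1))
        y = np.concatenate([np.ones(15), np.zeros(15)])
        m = fit_brt(X, y, BRTConfig(learning_rate=0.05, max_trees=10, step=5, seed=0),
                    feature_names=["a"])
        m.n_trees_opt = 0
        smap = predict_map(m, stack)
        np.testing.assert_allclose(smap.values, _sigmoid(m.intercept))

    def test_identical_stacks_identical_maps(self, rng):
        grid = Grid(4, 5, 0, 0, 1.0)
        vals = rng.normal(size=(4, 5))
        s1 = make_stack(grid, {"a": vals})
        s2 = make_stack(grid, {"a": vals.copy()}, period="other")
        X = rng.normal(size=(40, 1))
        y = np.concatenate([np.ones(20), np.zeros(20)])
        m = fit_brt(X, y, BRTConfig(learning_rate=0.05, max_trees=20, step=5, seed=1),
                    feature_names=["a"])
        np.testing.assert_array_equal(predict_map(m, s1).values,
                                      predict_map(m, s2).values)

    def test_missing_predictor_rejected(self, rng):
        grid = Grid(3, 3, 0, 0, 1.0)
        stack = make_stack(grid, {"other": np.zeros((3, 3))})
        X = rng.normal(size=(20, 1))
        y = np.concatenate([np.ones(10), np.zeros(10)])
        m = fit_brt(X, y, BRTConfig(max_trees=5, step=5, seed=0), feature_names=["a"])
        with pytest.raises(ValueError, match="lacks model predictors"):
            predict_map(m, stack)
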