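"""The three suitability algorithms: feature building, fitting contracts,
prediction and permutation importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import orchidsdm as o
from orchidsdm.models import FeatureSchema, extract_table


def table_from(arrs: dict) -> pd.DataFrame:
    return pd.DataFrame(arrs)


class TestBuildFeatures:
    def test_two_continuous_glm_gives_three_columns(self):
        t = table_from({"a": np.arange(10.0), "b": np.arange(10.0) ** 2})
        schema = FeatureSchema.fit(t, interactions=True)
        assert schema.transform(t).shape[1] == 3

    def test_four_mains_give_six_interactions(self):
        t = table_from({f"x{i}": np.random.default_rng(i).normal(size=8) for i in range(4)})
        schema = FeatureSchema.fit(t, interactions=True)
        assert schema.transform(t).shape[1] == 4 + 6

    def test_categorical_one_hot_sums_to_one(self):
        t = table_from({"veg": np.array([1, 2, 3, 1, 2])})
        schema = FeatureSchema.fit(t, categorical=("veg",))
        X = schema.transform(t)
        assert X.shape[1] == 3
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_same_categorical_interactions_excluded(self):
        t = table_from(
            {"a": np.random.default_rng(0).normal(size=9),
             "veg": np.array([1, 2, 3, 1, 2, 3, 1, 2, 3])}
        )
        schema = FeatureSchema.fit(t, categorical=("veg",), interactions=True)
        # mains: 1 cont + 3 onehot; interactions: a*v1, a*v2, a*v3 only
        assert schema.transform(t).shape[1] == 4 + 3

    def test_unseen_category_encoded_all_zero_with_warning(self):
        t = table_from({"veg": np.array([1, 2, 1, 2])})
        schema = FeatureSchema.fit(t, categorical=("veg",))
        with pytest.warns(UserWarning, match="unseen"):
            X = schema.transform(table_from({"veg": np.array([3])}))
        assert np.allclose(X, 0.0)


class TestGLM:
    def test_separable_toy_reaches_training_auc_one(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(-2, -0.1, 50), rng.uniform(0.1, 2, 50)])
        y = (x > 0).astype(int)
        model = o.fit_glm(x[:, None], y)
        assert o.auc(model.predict_matrix(x[:, None]), y) == 1.0

    def test_recovers_known_logistic_coefficients(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(1 + 2 * x)))
        y = (rng.random(5000) < p).astype(int)
        model = o.fit_glm(x[:, None], y)
        assert model.estimator.intercept_[0] == pytest.approx(1.0, abs=0.15)
        assert model.estimator.coef_[0, 0] == pytest.approx(2.0, abs=0.15)

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2000, 3))
        y = rng.integers(0, 2, 2000)
        model = o.fit_glm(x, y)
        assert o.auc(model.predict_matrix(x), y) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            o.fit_glm(np.zeros((10, 1)), np.ones(10))


class TestRF:
    def test_xor_pattern_learned(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, size=(400, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        model = o.fit_rf(X, y, o.ModelSpec("rf", n_trees=200, seed=0))
        assert o.auc(model.predict_matrix(X), y) > 0.95

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] > 0).astype(int)
        spec = o.ModelSpec("rf", n_trees=50, seed=7)
        p1 = o.fit_rf(X, y, spec).predict_matrix(X)
        p2 = o.fit_rf(X, y, o.ModelSpec("rf", n_trees=50, seed=7)).predict_matrix(X)
        assert np.array_equal(p1, p2)

    def test_predictions_bounded(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        p = o.fit_rf(X, y, o.ModelSpec("rf", n_trees=30)).predict_matrix(X)
        assert p.min() >= 0 and p.max() <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            o.fit_rf(np.zeros((10, 1)), np.zeros(10))


class TestMaxent:
    def test_fitted_response_monotone_in_driving_layer(self):
        rng = np.random.default_rng(6)
        bg = rng.uniform(0, 1, size=(800, 1))
        pres = rng.uniform(0.7, 1, size=(300, 1))
        model = o.fit_maxent(pres, bg)
        xs = np.linspace(0.05, 0.95, 10)[:, None]
        p = model.predict_matrix(xs)
        assert (np.diff(p) >= -1e-9).all()

    def test_zero_signal_gives_near_uniform_suitability(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(1000, 3))
        pres = rng.normal(size=(300, 3))
        model = o.fit_maxent(pres, bg)
        p = model.predict_matrix(rng.normal(size=(2000, 3)))
        assert p.std() < 0.05

    def test_background_doubling_barely_changes_ranking(self):
        rng = np.random.default_rng(8)
        bg = rng.normal(size=(1000, 2))
        pres = rng.normal(size=(200, 2)) + np.array([1.0, 0.5])
        grid_pts = rng.normal(size=(500, 2))
        p1 = o.fit_maxent(pres, bg).predict_matrix(grid_pts)
        p2 = o.fit_maxent(pres, np.vstack([bg, rng.normal(size=(1000, 2))])).predict_matrix(grid_pts)
        rho = stats.spearmanr(p1, p2).statistic
        assert 1 - rho < 0.02

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            o.fit_maxent(np.zeros((5, 1)), np.zeros((0, 1)))


class TestPredictSuitability:
    def test_constant_predictors_give_constant_suitability(self, stack):
        g = stack.grid
        const_stack = o.PredictorStack(
            {
                name: o.Raster(
                    g,
                    np.full(g.shape, 2.0)
                    if not stack[name].categorical
                    else np.full(g.shape, 1, dtype=np.uint8),
                    categorical=stack[name].categorical,
                )
                for name in stack.names
            }
        )
        rng = np.random.default_rng(0)
        cells = rng.choice(g.n_cells, 200, replace=False)
        labels = rng.integers(0, 2, 200)
        # train on varying data, predict on constant landscape
        model = o.train_model("glm", stack, cells, labels)
        with np.errstate(all="ignore"):
            pred = o.predict_suitability(model, const_stack)
        vals = pred.masked_values()
        assert np.allclose(vals, vals[0])

    def test_schema_mismatch_error_lists_missing_layers(self, stack):
        rng = np.random.default_rng(1)
        cells = rng.choice(stack.grid.n_cells, 100, replace=False)
        labels = rng.integers(0, 2, 100)
        model = o.train_model("glm", stack, cells, labels)
        with pytest.raises(ValueError, match="hi"):
            o.predict_suitability(model, stack.drop("hi"))

    def test_masked_cells_stay_masked_and_range_correct(self, stack):
        g = stack.grid
        layers = {n: stack[n] for n in stack.names}
        m = layers["bio1"].mask.copy()
        m[0, :] = False
        layers["bio1"] = o.Raster(g, layers["bio1"].values, m)
        holed = o.PredictorStack(layers)
        rng = np.random.default_rng(2)
        cells = rng.choice(np.flatnonzero(holed.joint_mask().ravel()), 150, replace=False)
        labels = rng.integers(0, 2, 150)
        for alg in ("glm", "rf", "maxent"):
            spec = o.ModelSpec(alg, n_trees=30)
            model = o.train_model(alg, holed, cells, labels, spec)
            pred = o.predict_suitability(model, holed)
            assert not pred.mask[0, :].any()
            v = pred.masked_values()
            assert v.min() >= 0 and v.max() <= 1


@pytest.fixture(scope="module")
def fitted_toy():
    rng = np.random.default_rng(9)
    n = 1500
    table = pd.DataFrame(
        {"signal": rng.normal(size=n), "noise": rng.normal(size=n)}
    )
    p = 1 / (1 + np.exp(-(2.5 * table["signal"] - 0.5)))
    labels = (rng.random(n) < p).astype(int)
    schema = FeatureSchema.fit(table)
    X = schema.transform(table)
    model = o.fit_glm(X, labels, schema=schema)
    return model, table, labels


class TestVariableImportance:
    def test_noise_predictor_has_near_zero_importance(self, fitted_toy):
        model, table, labels = fitted_toy
        imp = o.variable_importance(model, table, labels, seed=1, n_perm=10)
        noise_imp = imp.set_index("predictor").loc["noise", "importance"]
        assert abs(noise_imp) < 0.02

    def test_generating_predictor_ranks_first(self, fitted_toy):
        model, table, labels = fitted_toy
        imp = o.variable_importance(model, table, labels, seed=1, n_perm=10)
        assert imp.iloc[0]["predictor"] == "signal"

    def test_ranking_stable_across_permutation_seeds(self, fitted_toy):
        model, table, labels = fitted_toy
        a = o.variable_importance(model, table, labels, seed=1, n_perm=50)
        b = o.variable_importance(model, table, labels, seed=2, n_perm=50)
        assert a["predictor"].tolist() == b["predictor"].tolist()


@pytest.mark.parametrize("alg", ["glm", "rf", "maxent"])
def test_all_algorithms_bounded_and_better_than_random(stack, alg):
    """Held-out AUC lies in [0.45, 1] on a non-degenerate synthetic dataset."""
    niche = o.default_niches()["terrestrial"]
    occ = o.generate_occurrences(stack, niche, seed=13)
    from orchidsdm.prep import occurrence_cells, sample_pseudo_absence, split_train_test
    from orchidsdm.prep import thin_occurrences

    cells = occurrence_cells(thin_occurrences(occ, stack.grid), stack.grid)
    (pa,) = sample_pseudo_absence(stack.grid, cells, n=500, n_sets=1, seed=3)
    all_cells = np.concatenate([cells, pa])
    labels = np.concatenate([np.ones(cells.size, int), np.zeros(pa.size, int)])
    (tr, te), *_ = split_train_test(labels, n_repeats=1, seed=5)
    spec = o.ModelSpec(alg, n_trees=200)
    model = o.train_model(alg, stack, all_cells[tr], labels[tr], spec)
    scores = model.predict_table(extract_table(stack, all_cells[te]))
    assert scores.min() >= 0 and scores.max() <= 1
    assert 0.45 <= o.auc(scores, labels[te]) <= 1.0
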