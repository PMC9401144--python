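"""Strength aggregation, OLS inference, trees, forests, boosting, CV."""

import numpy as np
import pytest

import carenet as cn
from carenet.regression import (
    arithmetic_mean_strength,
    cv_r2,
    fit_linear,
    fit_lsboost,
    fit_random_forest,
    fit_tree,
    geometric_mean_strength,
    linear_spec,
    optimize_ensemble,
)


def test_geometric_mean_strength_values():
    assert geometric_mean_strength(["a"], {"a": 3.0}) == pytest.approx(3.0)
    assert geometric_mean_strength(["a", "b"], {"a": 4.0, "b": 9.0}) == pytest.approx(6.0)
    assert geometric_mean_strength(["a", "b", "c"],
                                   {"a": 1.0, "b": 1.0, "c": 8.0}) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        geometric_mean_strength(["a"], {"a": 0.0})
    with pytest.raises(ValueError):
        geometric_mean_strength([], {})


def test_arithmetic_mean_strength(rng):
    assert arithmetic_mean_strength(["a", "b"], {"a": 4.0, "b": 9.0}) == 6.5
    assert arithmetic_mean_strength(["a"], {"a": 5.5}) == 5.5
    vals = rng.random(6)
    s = {f"n{i}": v for i, v in enumerate(vals)}
    assert arithmetic_mean_strength(list(s), s) == pytest.approx(vals.mean())


def test_ols_exact_cases():
    x = np.arange(10, dtype=float)
    fit = fit_linear(x, 2 * x, names=["x"])
    assert fit.coef.loc["x", "coefficient"] == pytest.approx(2.0)
    assert fit.r2 == pytest.approx(1.0)
    fit = fit_linear(x, np.full(10, 3.0), names=["x"])
    assert fit.coef.loc["x", "coefficient"] == pytest.approx(0.0)
    assert fit.r2 == pytest.approx(0.0)


def test_ols_hand_computed_example():
    fit = fit_linear(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0]))
    assert fit.coef.iloc[1]["coefficient"] == pytest.approx(1.5)
    assert fit.coef.iloc[0]["coefficient"] == pytest.approx(-1 / 6)
    assert fit.r2 == pytest.approx(27 / 28)


def test_ols_matches_normal_equations(rng):
    for _ in range(10):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        fit = fit_linear(X, y)
        A = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(fit.coef["coefficient"].to_numpy(), beta, atol=1e-10)


def test_ols_rank_deficiency_names_columns():
    X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
    with pytest.raises(ValueError, match="dup"):
        fit_linear(X, np.arange(10.0), names=["x", "dup"])


def test_cv_r2_perfect_and_mean_only_models():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 2))
    y = X @ np.array([2.0, -1.0]) + 3.0
    assert cv_r2(linear_spec, X, y, k=5, seed=1) == pytest.approx(1.0)

    def mean_spec(X_tr, y_tr):
        mu = y_tr.mean()
        return lambda X_: np.full(len(X_), mu)

    assert cv_r2(mean_spec, X, y, k=5, seed=1) <= 0.0
    y_noisy = y + rng.normal(size=60)
    a = cv_r2(linear_spec, X, y_noisy, k=5, seed=2)
    b = cv_r2(linear_spec, X, y_noisy, k=5, seed=2)
    assert a == b  # seeded reproducibility
    with pytest.raises(ValueError):
        cv_r2(linear_spec, X, y, k=1)


def test_tree_constant_target_single_leaf():
    t = fit_tree(np.arange(8.0), np.full(8, 5.0))
    assert t.n_splits == 0
    assert np.allclose(t.predict(np.array([[0.0], [7.0]])), 5.0)


def test_tree_finds_step_split():
    x = np.linspace(-1, 1, 20)
    y = (x >= 0).astype(float)
    t = fit_tree(x, y, n_min=1, s_max=1)
    assert t.n_splits == 1
    assert -0.11 < t.threshold[0] < 0.01
    assert np.allclose(t.predict(np.array([[-0.5]])), 0.0)
    assert np.allclose(t.predict(np.array([[0.5]])), 1.0)


def test_tree_matches_exhaustive_oracle(rng):
    """Full-feature greedy tree equals exhaustive split search on tiny 1-D data."""
    def oracle_sse(x, y):
        # best single split by brute force
        best = (np.inf, None)
        xs = np.sort(np.unique(x))
        for a, b in zip(xs, xs[1:]):
            thr = (a + b) / 2
            l, r = y[x <= thr], y[x > thr]
            sse = ((l - l.mean()) ** 2).sum() + ((r - r.mean()) ** 2).sum()
            if sse < best[0] - 1e-12:
                best = (sse, thr)
        return best

    for _ in range(25):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        t = fit_tree(x, y, n_min=1, s_max=1)
        sse_o, thr_o = oracle_sse(x, y)
        if t.n_splits == 0:
            assert thr_o is None
            continue
        mask = x <= t.threshold[0]
        sse_t = (((y[mask] - y[mask].mean()) ** 2).sum()
                 + ((y[~mask] - y[~mask].mean()) ** 2).sum())
        assert sse_t == pytest.approx(sse_o, abs=1e-9)


def test_tree_prediction_is_leaf_training_mean(rng):
    X = rng.normal(size=(50, 2))
    y = rng.normal(size=50)
    t = fit_tree(X, y, n_min=5, s_max=4, rng=0)
    pred = t.predict(X)
    for leaf in np.unique(pred):
        assert leaf == pytest.approx(y[pred == leaf].mean())


def test_forest_reduces_to_single_tree_without_bootstrap(rng):
    X = rng.normal(size=(40, 2))
    y = rng.normal(size=40)
    ens = fit_random_forest(X, y, M=1, bootstrap=False, seed=3, n_min=5, s_max=4)
    single = fit_tree(X, y, n_min=5, s_max=4, rng=np.random.default_rng(3))
    assert np.allclose(ens.predict(X), single.predict(X))


def test_forest_prediction_is_mean_of_trees(rng):
    X = rng.normal(size=(60, 2))
    y = rng.normal(size=60)
    ens = fit_random_forest(X, y, M=7, seed=1)
    manual = np.mean([t.predict(X) for t in ens.trees], axis=0)
    assert np.allclose(ens.predict(X), manual)


def test_forest_learns_step_function():
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, size=200)
    y = (x >= 0).astype(float)
    ens = fit_random_forest(x, y, M=50, seed=4, n_min=2, s_max=8)
    pred = ens.predict(x)
    r2 = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert r2 >= 0.9


def test_lsboost_zero_rounds_is_mean_predictor(rng):
    X = rng.normal(size=(30, 2))
    y = rng.normal(size=30)
    ens = fit_lsboost(X, y, M=0)
    assert np.allclose(ens.predict(X), y.mean())


def test_lsboost_one_full_step_stump_zeroes_step_residuals():
    x = np.linspace(-1, 1, 30)
    y = np.where(x < 0, 0.0, 1.0)
    ens = fit_lsboost(x, y, M=1, eta=1.0, n_min=1, s_max=1)
    assert np.allclose(ens.predict(x), y, atol=1e-12)


def test_lsboost_training_loss_nonincreasing(rng):
    X = rng.normal(size=(80, 3))
    y = X[:, 0] ** 2 + rng.normal(scale=0.3, size=80)
    for eta in (0.1, 0.5, 1.0):
        ens = fit_lsboost(X, y, M=15, eta=eta, n_min=4, s_max=6)
        losses = ens.train_loss
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


def test_lsboost_degenerate_single_leaf_learner_fixed_point(rng):
    """Single-leaf trees fit the residual mean (which is 0), leaving the
    overall prediction at mean(y)."""
    X = rng.normal(size=(25, 1))
    y = rng.normal(size=25)
    ens = fit_lsboost(X, y, M=5, eta=1.0, n_min=25, s_max=0)
    assert np.allclose(ens.predict(X), y.mean(), atol=1e-12)


def test_optimize_ensemble_budget_and_trace(rng):
    X = rng.normal(size=(60, 2))
    y = X[:, 0] + rng.normal(scale=0.2, size=60)
    best, trace = optimize_ensemble(X, y, budget=1, seed=0)
    assert len(trace) == 1
    assert best["cv_rmse"] == trace["cv_rmse"].iloc[0]
    best, trace = optimize_ensemble(X, y, budget=6, seed=0)
    assert best["cv_rmse"] == trace["cv_rmse"].min()
    with pytest.raises(ValueError):
        optimize_ensemble(X, y, budget=0)


def test_compare_models_shapes_and_common_rows(small_network, small_cases):
    s = cn.strengths(small_network)
    table = cn.compare_models(small_cases, s, small_network, seed=0,
                              n_embedding_draws=2,
                              walk=cn.WalkParams(t=2, l=10, p=4, q=0.25),
                              d=8, w=3, epochs=2)
    assert list(table["model"]) == ["Model 1", "Model 2", "Model 3",
                                    "Model 3", "Model 4", "Model 4"]
    assert (table["adj_cv_r2"] <= table["cv_r2"] + 1e-12).all()
    best3 = table[(table["model"] == "Model 3") & (table["statistic"] == "best")]
    mean3 = table[(table["model"] == "Model 3") & (table["statistic"] == "mean")]
    assert best3["cv_r2"].iloc[0] >= mean3["cv_r2"].iloc[0]


def test_model1_slope_recovery_is_negative(small_world, small_network, small_cases):
    s = cn.strengths(small_network)
    mu = np.array([geometric_mean_strength(h.split(";"), s)
                   for h in small_cases["H"]])
    fit = fit_linear(mu, small_cases["D_in"].to_numpy(float), names=["mu_g_s"])
    assert fit.coef.loc["mu_g_s", "coefficient"] < 0
    assert fit.coef.loc["mu_g_s", "p_value"] < 0.05
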