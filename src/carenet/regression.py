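"""Regression models linking cooperation features to the duration of stay.

Model 1: OLS of D^in on the geometric mean of strength mu_G(s) over the
hospitals of a case.  Model 2 adds age at admission.  Model 3 regresses
D^in on the mean node2vec vector of the hospitals.  Model 4 replaces OLS by
a regression-tree ensemble (random forest or least-squares boosting), with
a budgeted hyperparameter search standing in for the full Bayesian
optimization stage.  Performance is compared by cross-validated R^2 pooled
over out-of-fold predictions on identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

from .embedding import EmbeddingModel, case_embedding, embed_network, rmse, WalkParams

__all__ = [
    "geometric_mean_strength",
    "arithmetic_mean_strength",
    "LinearFit",
    "fit_linear",
    "cv_r2",
    "RegressionTree",
    "fit_tree",
    "TreeEnsemble",
    "fit_random_forest",
    "fit_lsboost",
    "predict_ensemble",
    "optimize_ensemble",
    "compare_models",
]


def geometric_mean_strength(H, strengths: dict[str, float]) -> float:
    """mu_G(s): geometric mean of strengths over the hospitals of a case,
    computed in the log domain."""
    vals = np.array([strengths[h] for h in H], dtype=float)
    if len(vals) == 0:
        raise ValueError("empty provider set")
    if np.any(vals <= 0):
        raise ValueError("strengths must be positive for a geometric mean")
    return float(np.exp(np.mean(np.log(vals))))


def arithmetic_mean_strength(H, strengths: dict[str, float]) -> float:
    """mu(s): plain mean of strengths, for the sensitivity comparison."""
    vals = [strengths[h] for h in H]
    if not vals:
        raise ValueError("empty provider set")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# linear model


@dataclass
class LinearFit:
    """OLS summary: per-coefficient inference plus fit statistics."""

    coef: pd.DataFrame  # index: term; columns: coefficient, std_error, t, p_value
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    n: int
    model: object = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.model.predict(sm.add_constant(X, has_constant="add"))


def fit_linear(X, y, names: list[str] | None = None) -> LinearFit:
    """Ordinary least squares with t tests per coefficient and the overall
    F test; raises on a rank-deficient design, naming the collinear columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} observations, got {n}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        cur = design[:, :1]
        for j in range(1, design.shape[1]):
            trial = np.column_stack([cur, design[:, j]])
            if np.linalg.matrix_rank(trial) == cur.shape[1]:
                bad.append(names[j - 1] if names else f"x{j}")
            else:
                cur = trial
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    constant_y = float(np.var(y)) == 0.0  # intercept alone is exact: R^2 := 0
    terms = ["(Intercept)"] + (names if names else [f"x{j + 1}" for j in range(k)])
    coef = pd.DataFrame(
        {
            "coefficient": res.params,
            "std_error": res.bse,
            "t": res.tvalues,
            "p_value": res.pvalues,
        },
        index=terms,
    )
    return LinearFit(
        coef=coef,
        r2=0.0 if constant_y else float(res.rsquared),
        adj_r2=0.0 if constant_y else float(res.rsquared_adj),
        f_stat=float("nan") if constant_y else float(res.fvalue),
        f_pvalue=float("nan") if constant_y else float(res.f_pvalue),
        n=n,
        model=res,
    )


def cv_r2(model_spec, X, y, k: int = 5, repeats: int = 1, seed: int = 0) -> float:
    """Cross-validated R^2: pool out-of-fold predictions over the k folds and
    score them against y; average over ``repeats`` reshuffles.

    ``model_spec(X_train, y_train)`` must return a ``predict(X) -> yhat``
    callable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError("more folds than observations")
    scores = []
    for r in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=(seed + r) % 2**31)
        pred = np.empty_like(y)
        for tr, te in kf.split(X):
            predictor = model_spec(X[tr], y[tr])
            pred[te] = predictor(X[te])
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        scores.append(1.0 - ss_res / ss_tot)
    return float(np.mean(scores))


def linear_spec(X_tr, y_tr):
    beta, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(len(X_tr)), X_tr]), y_tr, rcond=None
    )
    return lambda X: np.column_stack([np.ones(len(X)), X]) @ beta


# ---------------------------------------------------------------------------
# regression trees


@dataclass
class RegressionTree:
    """Binary regression tree stored as parallel arrays (-1 marks a leaf)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_splits: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = np.empty(len(X))
        for i, x in enumerate(X):
            node = 0
            while self.feature[node] >= 0:
                node = (self.left[node] if x[self.feature[node]] <= self.threshold[node]
                        else self.right[node])
            out[i] = self.value[node]
        return out


def _best_split(X, y, feats, n_min):
    """Exhaustive best (feature, threshold) by SSE reduction among ``feats``;
    ties broken toward the lower feature index then lower threshold."""
    best = None  # (sse, feat, thr)
    for f in feats:
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        n = len(ys)
        total_sum, total_sq = csum[-1], csq[-1]
        # candidate split after position i (1-based left size)
        sizes = np.arange(1, n)
        valid = (xs[1:] > xs[:-1]) & (sizes >= n_min) & ((n - sizes) >= n_min)
        if not valid.any():
            continue
        ls, rs = csum[:-1], total_sum - csum[:-1]
        lq, rq = csq[:-1], total_sq - csq[:-1]
        sse = (lq - ls**2 / sizes) + (rq - rs**2 / (n - sizes))
        sse = np.where(valid, sse, np.inf)
        i = int(np.argmin(sse))  # argmin takes the first == lowest threshold
        cand = (float(sse[i]), int(f), float((xs[i] + xs[i + 1]) / 2.0))
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    return best


def fit_tree(
    X,
    y,
    n_min: int = 5,
    s_max: int = 30,
    m_try: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> RegressionTree:
    """Greedy SSE-minimizing binary tree.

    At each node ``m_try`` candidate features are drawn at random, the best
    variable and split point among them is chosen, and the node is split;
    growth stops when leaves reach ``n_min`` samples or the tree reaches
    ``s_max`` splits.  Leaf values are training means.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    k = X.shape[1]
    m_try = k if m_try is None else min(m_try, k)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    feature, threshold, left, right, value = [], [], [], [], []

    def new_node(idx):
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(float(y[idx].mean()))
        return len(feature) - 1

    root_idx = np.arange(len(y))
    queue = [(new_node(root_idx), root_idx)]
    n_splits = 0
    while queue and n_splits < s_max:
        node, idx = queue.pop(0)
        if len(idx) < 2 * n_min or np.ptp(y[idx]) == 0.0:
            continue
        feats = np.sort(rng.choice(k, size=m_try, replace=False))
        found = _best_split(X[idx], y[idx], feats, n_min)
        if found is None:
            continue
        _, f, thr = found
        mask = X[idx, f] <= thr
        li, ri = idx[mask], idx[~mask]
        feature[node] = f
        threshold[node] = thr
        left[node] = new_node(li)
        right[node] = new_node(ri)
        n_splits += 1
        queue.append((left[node], li))
        queue.append((right[node], ri))

    return RegressionTree(
        feature=np.array(feature),
        threshold=np.array(threshold),
        left=np.array(left),
        right=np.array(right),
        value=np.array(value),
        n_splits=n_splits,
    )


@dataclass
class TreeEnsemble:
    """Bagged or boosted regression trees."""

    method: str  # "random_forest" | "lsboost"
    trees: list[RegressionTree]
    M: int
    eta: float = 1.0
    f0: float = 0.0
    n_min: int = 5
    s_max: int = 30
    m_try: int | None = None
    seed: int = 0
    train_loss: list[float] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return predict_ensemble(self, X)


def predict_ensemble(ens: TreeEnsemble, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if ens.method == "random_forest":
        if not ens.trees:
            raise ValueError("random forest with no trees")
        return np.mean([t.predict(X) for t in ens.trees], axis=0)
    pred = np.full(len(X), ens.f0)
    for t in ens.trees:
        pred += ens.eta * t.predict(X)
    return pred


def fit_random_forest(
    X,
    y,
    M: int = 100,
    n_min: int = 5,
    s_max: int = 30,
    m_try: int | None = None,
    seed: int = 0,
    bootstrap: bool = True,
) -> TreeEnsemble:
    """Random forest: M trees on n-out-of-n bootstrap resamples, predictions
    averaged."""
    if M < 1:
        raise ValueError("M must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(M):
        idx = rng.integers(0, len(y), size=len(y)) if bootstrap else np.arange(len(y))
        trees.append(fit_tree(X[idx], y[idx], n_min=n_min, s_max=s_max,
                              m_try=m_try, rng=rng))
    return TreeEnsemble(method="random_forest", trees=trees, M=M,
                        n_min=n_min, s_max=s_max, m_try=m_try, seed=seed)


def fit_lsboost(
    X,
    y,
    M: int = 100,
    eta: float = 0.1,
    n_min: int = 5,
    s_max: int = 10,
    m_try: int | None = None,
    seed: int = 0,
) -> TreeEnsemble:
    """Least-squares boosting: start from the mean, then repeatedly fit a
    tree to the current residuals and add it scaled by the learning rate
    ``eta``.  Under squared loss the leaf constants are leaf residual means,
    which is what the residual-fitted tree already stores."""
    if M < 0:
        raise ValueError("M must be >= 0")
    if not 0.0 < eta <= 1.0:
        raise ValueError("eta must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    f0 = float(y.mean())
    pred = np.full(len(y), f0)
    trees: list[RegressionTree] = []
    loss = [float(0.5 * np.mean((y - pred) ** 2))]
    for _ in range(M):
        resid = y - pred
        t = fit_tree(X, resid, n_min=n_min, s_max=s_max, m_try=m_try, rng=rng)
        pred = pred + eta * t.predict(X)
        trees.append(t)
        loss.append(float(0.5 * np.mean((y - pred) ** 2)))
    return TreeEnsemble(method="lsboost", trees=trees, M=M, eta=eta, f0=f0,
                        n_min=n_min, s_max=s_max, m_try=m_try, seed=seed,
                        train_loss=loss)


def optimize_ensemble(
    X, y, budget: int = 30, seed: int = 0, folds: int = 5
) -> tuple[dict, pd.DataFrame]:
    """Budgeted search over {random_forest, lsboost} x hyperparameters
    minimizing k-fold CV RMSE; a seeded random search (the configuration
    space is small enough that a surrogate model buys little at desk scale).
    Returns (incumbent, trace)."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    k = X.shape[1]
    rows = []
    for b in range(budget):
        method = "random_forest" if rng.random() < 0.5 else "lsboost"
        params = {
            "M": int(rng.integers(20, 121)),
            "n_min": int(rng.integers(2, 16)),
            "s_max": int(rng.integers(4, 41)),
            "m_try": int(rng.integers(1, k + 1)),
            "seed": int(rng.integers(0, 2**31)),
        }
        if method == "lsboost":
            params["eta"] = float(rng.uniform(0.05, 1.0))

        def spec(X_tr, y_tr, method=method, params=params):
            fit = fit_random_forest if method == "random_forest" else fit_lsboost
            ens = fit(X_tr, y_tr, **params)
            return ens.predict

        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = np.empty_like(y)
        for tr, te in kf.split(X):
            pred[te] = spec(X[tr], y[tr])(X[te])
        rows.append({"trial": b, "method": method, **params,
                     "cv_rmse": rmse(y, pred)})
    trace = pd.DataFrame(rows)
    best = trace.loc[trace["cv_rmse"].idxmin()].to_dict()
    return best, trace


# ---------------------------------------------------------------------------
# the four-model comparison


def _adj(r2: float, n: int, k: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def compare_models(
    cases: pd.DataFrame,
    strengths: dict[str, float],
    G,
    seed: int = 0,
    folds: int = 5,
    n_embedding_draws: int = 20,
    walk: WalkParams | None = None,
    d: int = 16,
    w: int = 5,
    epochs: int = 3,
    ensemble_params: dict | None = None,
    optimize_budget: int = 0,
) -> pd.DataFrame:
    """Cross-validated R^2 of Models 1-4 on identical folds.

    Models 3 and 4 are reported as the mean and best over
    ``n_embedding_draws`` independent embedding re-draws.  Model 4 uses a
    fixed LSBoost configuration by default; pass ``optimize_budget > 0`` to
    let the budgeted hyperparameter search pick the ensemble per draw.
    """
    H_sets = [h.split(";") for h in cases["H"]]
    y = cases["D_in"].to_numpy(dtype=float)
    n = len(y)
    mu_g = np.array([geometric_mean_strength(H, strengths) for H in H_sets])
    age = cases["age"].to_numpy(dtype=float)
    walk = walk or WalkParams()
    ens = dict(M=60, eta=0.1, n_min=8, s_max=12)
    ens.update(ensemble_params or {})

    r2_1 = cv_r2(linear_spec, mu_g, y, k=folds, seed=seed)
    r2_2 = cv_r2(linear_spec, np.column_stack([mu_g, age]), y, k=folds, seed=seed)

    r2_3, r2_4 = [], []
    for draw in range(n_embedding_draws):
        es = (seed * 2003 + draw) % 2**31
        model = embed_network(
            G, WalkParams(t=walk.t, l=walk.l, p=walk.p, q=walk.q, seed=es),
            d=d, w=w, epochs=epochs, seed=es,
        )
        X = np.vstack([case_embedding(H, model) for H in H_sets])
        r2_3.append(cv_r2(linear_spec, X, y, k=folds, seed=seed))
        if optimize_budget > 0:
            best, _ = optimize_ensemble(X, y, budget=optimize_budget,
                                        seed=es, folds=folds)
            method = best["method"]
            keys = ["M", "n_min", "s_max", "m_try", "seed"]
            params = {k_: int(best[k_]) for k_ in keys}
            if method == "lsboost":
                params["eta"] = float(best["eta"])

            def tree_spec(X_tr, y_tr, method=method, params=params):
                fit = fit_random_forest if method == "random_forest" else fit_lsboost
                return fit(X_tr, y_tr, **params).predict
        else:
            def tree_spec(X_tr, y_tr):
                return fit_lsboost(X_tr, y_tr, seed=es, **ens).predict
        r2_4.append(cv_r2(tree_spec, X, y, k=folds, seed=seed))

    def row(name, stat, r2, k):
        return {"model": name, "statistic": stat, "cv_r2": r2,
                "adj_cv_r2": _adj(r2, n, k)}

    rows = [
        row("Model 1", "", r2_1, 1),
        row("Model 2", "", r2_2, 2),
        row("Model 3", "mean", float(np.mean(r2_3)), d),
        row("Model 3", "best", float(np.max(r2_3)), d),
        row("Model 4", "mean", float(np.mean(r2_4)), d),
        row("Model 4", "best", float(np.max(r2_4)), d),
    ]
    return pd.DataFrame(rows)
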