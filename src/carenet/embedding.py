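"""node2vec from scratch: biased second-order walks and an exact-softmax
skip-gram, plus case-level feature aggregation and the RMSE grid search.

The walk is controlled by the return parameter ``p`` and the in-out
parameter ``q``: stepping from ``v`` after arriving from ``u``, the
unnormalized probability of moving to neighbor ``x`` is ``alpha * w_vx``
with ``alpha = 1/p`` if ``x == u``, ``1`` if ``x`` neighbors ``u`` and
``1/q`` otherwise (shortest-path distance 2 from ``u``).  Large ``p`` with
small ``q`` gives depth-first-like exploration.  The skip-gram objective is
maximized with exact softmax normalization over all nodes — affordable at
the few-hundred-node scale of provider networks — by minibatch stochastic
gradient ascent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WalkParams",
    "EmbeddingModel",
    "transition_probs",
    "biased_walks",
    "WalkSampler",
    "skipgram_objective",
    "train_skipgram",
    "embed_network",
    "case_embedding",
    "rmse",
    "grid_search",
]


@dataclass(frozen=True)
class WalkParams:
    """Second-order walk controls: t walks of l nodes from every node."""

    t: int = 7
    l: int = 60
    p: float = 16.0
    q: float = 1.0 / 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 1 or self.l < 1:
            raise ValueError("t and l must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class EmbeddingModel:
    """Per-node feature vectors v_u plus training metadata."""

    vectors: dict[str, np.ndarray]
    d: int
    w: int
    meta: dict = field(default_factory=dict)


def transition_probs(G: nx.Graph, prev, cur, p: float, q: float):
    """Normalized next-step distribution from ``cur`` given previous node
    ``prev`` (``None`` on the first step, which is weight-proportional).

    Returns (neighbors, probabilities).
    """
    nbrs = list(G.neighbors(cur))
    if not nbrs:
        raise ValueError(f"node {cur!r} is isolated; cannot step")
    w = np.array([G[cur][x].get("weight", 1.0) for x in nbrs], dtype=float)
    if prev is None:
        probs = w / w.sum()
        return nbrs, probs
    prev_nbrs = set(G.neighbors(prev))
    alpha = np.empty(len(nbrs))
    for i, x in enumerate(nbrs):
        if x == prev:
            alpha[i] = 1.0 / p
        elif x in prev_nbrs:
            alpha[i] = 1.0
        else:
            alpha[i] = 1.0 / q
    pi = alpha * w
    return nbrs, pi / pi.sum()


class WalkSampler:
    """Second-order walker with cached per-(prev, cur) distributions."""

    def __init__(self, G: nx.Graph, p: float, q: float) -> None:
        self.G = G
        self.p = p
        self.q = q
        self._cache: dict[tuple, tuple[list, np.ndarray]] = {}

    def _dist(self, prev, cur):
        key = (prev, cur)
        hit = self._cache.get(key)
        if hit is None:
            nbrs, probs = transition_probs(self.G, prev, cur, self.p, self.q)
            hit = (nbrs, np.cumsum(probs))
            self._cache[key] = hit
        return hit

    def step(self, prev, cur, rng: np.random.Generator):
        nbrs, cum = self._dist(prev, cur)
        return nbrs[int(np.searchsorted(cum, rng.random(), side="right"))]

    def walk(self, start, length: int, rng: np.random.Generator) -> list:
        seq = [start]
        prev = None
        for _ in range(length - 1):
            nxt = self.step(prev, seq[-1], rng)
            prev = seq[-1]
            seq.append(nxt)
        return seq


def biased_walks(G: nx.Graph, params: WalkParams) -> list[list]:
    """The walk corpus: ``t`` seeded walks of ``l`` nodes from every node."""
    rng = np.random.default_rng(params.seed)
    sampler = WalkSampler(G, params.p, params.q)
    nodes = sorted(G.nodes)
    corpus = []
    for _ in range(params.t):
        for n in nodes:
            corpus.append(sampler.walk(n, params.l, rng))
    return corpus


# ---------------------------------------------------------------------------
# skip-gram


def _corpus_pairs(corpus: list[list], index: dict, w: int) -> np.ndarray:
    """(center, context) index pairs using the w nodes before and after."""
    pairs = []
    for walk in corpus:
        ids = [index[n] for n in walk]
        for i, u in enumerate(ids):
            lo, hi = max(0, i - w), min(len(ids), i + w + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((u, ids[j]))
    return np.asarray(pairs, dtype=np.int64) if pairs else np.empty((0, 2), dtype=np.int64)


def skipgram_objective(V: np.ndarray, pairs: np.ndarray):
    """Log-likelihood of the skip-gram model and its gradient w.r.t. V.

    The objective is the sum over (center u, context c) pairs of
    ``v_u . v_c - log Z_u`` with ``Z_u = sum_v exp(v_u . v_v)`` — the exact
    softmax likelihood the embedding maximizes.
    """
    n = V.shape[0]
    counts = np.zeros((n, n))
    np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 1.0)
    m = counts.sum(axis=1)  # center multiplicities
    scores = V @ V.T
    shift = scores.max(axis=1, keepdims=True)
    expS = np.exp(scores - shift)
    Z = expS.sum(axis=1)
    logZ = np.log(Z) + shift.ravel()
    P = expS / Z[:, None]
    obj = float((counts * scores).sum() - m @ logZ)
    grad = (counts + counts.T) @ V
    grad -= (m[:, None] * P) @ V
    grad -= P.T @ (m[:, None] * V)
    return obj, grad


def train_skipgram(
    corpus: list[list],
    d: int = 75,
    w: int = 13,
    epochs: int = 5,
    learning_rate: float = 0.5,
    seed: int = 0,
    batch_size: int = 512,
) -> EmbeddingModel:
    """Fit node vectors by minibatch stochastic gradient ascent on the exact
    softmax skip-gram likelihood.  The learning rate decays linearly to 1%
    of its initial value; initialization is small uniform noise."""
    if d < 1 or w < 1:
        raise ValueError("d and w must be >= 1")
    if not corpus:
        raise ValueError("empty corpus")
    nodes = sorted({n for walk in corpus for n in walk})
    index = {n: i for i, n in enumerate(nodes)}
    pairs = _corpus_pairs(corpus, index, w)
    if len(pairs) == 0:
        raise ValueError("corpus yields no training pairs (walks too short?)")
    rng = np.random.default_rng(seed)
    n = len(nodes)
    V = rng.uniform(-0.5 / d, 0.5 / d, size=(n, d))

    n_batches = max(1, int(np.ceil(len(pairs) / batch_size))) * epochs
    b = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for lo in range(0, len(pairs), batch_size):
            batch = pairs[order[lo:lo + batch_size]]
            lr = learning_rate * max(0.01, 1.0 - b / n_batches)
            b += 1
            centers, ctx = batch[:, 0], batch[:, 1]
            uniq, mult = np.unique(centers, return_counts=True)
            scores = V[uniq] @ V.T
            shift = scores.max(axis=1, keepdims=True)
            expS = np.exp(scores - shift)
            P = expS / expS.sum(axis=1, keepdims=True)
            grad = np.zeros_like(V)
            np.add.at(grad, centers, V[ctx])
            np.add.at(grad, ctx, V[centers])
            grad[uniq] -= (mult[:, None] * P) @ V
            grad -= P.T @ (mult[:, None] * V[uniq])
            V += (lr / len(batch)) * grad  # mean-gradient step for stability

    obj, _ = skipgram_objective(V, pairs)
    vectors = {nodes[i]: V[i].copy() for i in range(n)}
    return EmbeddingModel(
        vectors=vectors, d=d, w=w,
        meta={"epochs": epochs, "learning_rate": learning_rate, "seed": seed,
              "objective": obj, "n_pairs": int(len(pairs))},
    )


def embed_network(
    G: nx.Graph,
    walk: WalkParams | None = None,
    d: int = 75,
    w: int = 13,
    epochs: int = 5,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> EmbeddingModel:
    """Walks + skip-gram in one call (seeds both stages from ``seed``)."""
    walk = walk or WalkParams()
    wp = WalkParams(t=walk.t, l=walk.l, p=walk.p, q=walk.q, seed=seed)
    corpus = biased_walks(G, wp)
    return train_skipgram(corpus, d=d, w=w, epochs=epochs,
                          learning_rate=learning_rate, seed=seed)


# ---------------------------------------------------------------------------
# case aggregation and model selection


def case_embedding(H, model: EmbeddingModel) -> np.ndarray:
    """Case feature c_i: the mean vector of the hospitals in H_i."""
    missing = [h for h in H if h not in model.vectors]
    if missing:
        raise KeyError(
            f"providers without embeddings (outside the giant component?): {missing}"
        )
    return np.mean([model.vectors[h] for h in sorted(H)], axis=0)


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("rmse of empty sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def grid_search(
    G: nx.Graph,
    cases: pd.DataFrame,
    p_grid,
    q_grid,
    walk: WalkParams | None = None,
    d: int = 16,
    w: int = 5,
    folds: int = 5,
    iterations: int = 20,
    seed: int = 0,
    epochs: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """RMSE surface over (p, q): per cell, re-draw the embedding
    ``iterations`` times, run k-fold cross-validated linear regression of
    D^in on the case embedding, and average the test RMSE.  Returns the
    surface table (with per-iteration values retained) and the argmin cell.
    """
    from sklearn.model_selection import KFold

    p_grid, q_grid = list(p_grid), list(q_grid)
    if not p_grid or not q_grid:
        raise ValueError("empty grid")
    if folds > len(cases):
        raise ValueError("more folds than cases")
    walk = walk or WalkParams()
    H_sets = [h.split(";") for h in cases["H"]]
    y = cases["D_in"].to_numpy(dtype=float)
    rows = []
    for p in p_grid:
        for q in q_grid:
            vals = []
            for it in range(iterations):
                sub_seed = (seed * 1009 + it) % (2**31)
                model = embed_network(
                    G, WalkParams(t=walk.t, l=walk.l, p=p, q=q, seed=sub_seed),
                    d=d, w=w, epochs=epochs, seed=sub_seed,
                )
                X = np.vstack([case_embedding(H, model) for H in H_sets])
                kf = KFold(n_splits=folds, shuffle=True, random_state=sub_seed)
                fold_rmse = []
                for tr, te in kf.split(X):
                    beta, *_ = np.linalg.lstsq(
                        np.column_stack([np.ones(len(tr)), X[tr]]), y[tr], rcond=None
                    )
                    pred = np.column_stack([np.ones(len(te)), X[te]]) @ beta
                    fold_rmse.append(rmse(y[te], pred))
                vals.append(float(np.mean(fold_rmse)))
            rows.append({"p": p, "q": q, "mean_rmse": float(np.mean(vals)),
                         "sd_rmse": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "iteration_rmse": vals})
    surface = pd.DataFrame(rows)
    best = surface.loc[surface["mean_rmse"].idxmin()]
    return surface, {"p": float(best["p"]), "q": float(best["q"]),
                     "mean_rmse": float(best["mean_rmse"])}
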