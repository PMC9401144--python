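"""Two-level map-equation community detection and community-level analysis.

The map equation scores a partition by the description length of a random
walk on the weighted undirected graph: L = q H(Q) + sum_c p_c H(P_c), in
bits, where node visit rates are s_a / 2W, a community's exit probability is
its cut weight over 2W, H(Q) is the entropy of the exit distribution and
H(P_c) the entropy of within-community movement (including the exit).
Minimizing L with a Louvain-style greedy search (seeded node sweeps plus
community merges, two levels only) yields flow-based communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import network_features
from .regression import geometric_mean_strength

__all__ = [
    "CommunityPartition",
    "map_equation",
    "detect_communities",
    "community_features",
    "structure_vs_cooperation",
]


@dataclass
class CommunityPartition:
    """node -> community assignment with its map-equation value (bits)."""

    assignment: dict[str, int]
    L: float
    n_communities: int
    feature_table: pd.DataFrame | None = field(default=None, repr=False)


def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def _flow_arrays(G: nx.Graph, assignment: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(p_alpha per node, q_c exit prob per community, p_circ per community)."""
    nodes = list(G.nodes)
    comms = sorted(set(assignment.values()))
    cidx = {c: i for i, c in enumerate(comms)}
    W2 = 2.0 * sum(d.get("weight", 1.0) for _, _, d in G.edges(data=True))
    if W2 == 0:
        raise ValueError("graph has no edge weight")
    p = np.array([G.degree(n, weight="weight") / W2 for n in nodes])
    cut = np.zeros(len(comms))
    for u, v, dd in G.edges(data=True):
        cu, cv = cidx[assignment[u]], cidx[assignment[v]]
        if cu != cv:
            w = dd.get("weight", 1.0)
            cut[cu] += w
            cut[cv] += w
    q = cut / W2
    member_p = np.zeros(len(comms))
    for n, pa in zip(nodes, p):
        member_p[cidx[assignment[n]]] += pa
    if np.any(member_p == 0):
        raise ValueError("empty community in partition")
    return p, q, q + member_p


def map_equation(G: nx.Graph, assignment: dict) -> float:
    """Description length L of the partition, in bits (base-2 logs).

    Computed as q H(Q) + sum_c p_c H(P_c) with the entropies expanded:
    L = plogp(q) - 2 sum_c plogp(q_c) + sum_c plogp(p_circ_c)
        - sum_a plogp(p_a).
    """
    missing = [n for n in G.nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    p, q, p_circ = _flow_arrays(G, assignment)
    q_tot = float(q.sum())
    L = float(_plogp(q_tot)) - 2.0 * float(np.sum(_plogp(q)))
    L += float(np.sum(_plogp(p_circ))) - float(np.sum(_plogp(p)))
    return float(L)


# ---------------------------------------------------------------------------
# greedy two-level search


class _State:
    """Incremental bookkeeping for the greedy search.

    Maintains, per community c: S_c (sum of member visit rates) and
    q_c (exit probability = cut weight / 2W).  The node-level term
    sum_a plogp(p_a) is constant across partitions.
    """

    def __init__(self, G: nx.Graph, seed: int) -> None:
        self.G = G
        self.nodes = list(G.nodes)
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        self.W2 = 2.0 * sum(d.get("weight", 1.0) for _, _, d in G.edges(data=True))
        self.p = np.array([G.degree(n, weight="weight") / self.W2 for n in self.nodes])
        self.comm = np.arange(len(self.nodes))  # start from singletons
        self.S = self.p.copy()
        self.q = self.p.copy()  # singleton: every incident edge is an exit
        self.node_term = float(np.sum(_plogp(self.p)))
        self.rng = np.random.default_rng(seed)

    def node_comm_weight(self, n) -> dict[int, float]:
        """Visit-rate-scaled weight from node n into each community."""
        out: dict[int, float] = {}
        for x in self.G.neighbors(n):
            c = int(self.comm[self.idx[x]])
            out[c] = out.get(c, 0.0) + self.G[n][x].get("weight", 1.0) / self.W2
        return out

    def L(self) -> float:
        used = np.unique(self.comm)
        return self._L_of(self.q[used], self.S[used])

    def _L_of(self, q: np.ndarray, S: np.ndarray) -> float:
        q_tot = float(q.sum())
        return (float(_plogp(q_tot)) - 2.0 * float(np.sum(_plogp(q)))
                + float(np.sum(_plogp(q + S))) - self.node_term)

    def move(self, i: int, target: int, w_to: dict[int, float]) -> None:
        src = int(self.comm[i])
        pa = self.p[i]
        w_src = w_to.get(src, 0.0)
        w_tgt = w_to.get(target, 0.0)
        self.S[src] -= pa
        self.q[src] -= pa - 2.0 * w_src
        self.comm[i] = target
        self.S[target] += pa
        self.q[target] += pa - 2.0 * w_tgt


def detect_communities(G: nx.Graph, seed: int = 0, max_passes: int = 50) -> CommunityPartition:
    """Greedy minimization of the map equation, two levels only.

    Starting from singleton communities, seeded sweeps move nodes to the
    neighboring community that most decreases L (ties keep the current
    assignment); between sweeps, connected community pairs are merged while
    that decreases L.  Terminates at a local optimum.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    if G.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(G.nodes))}
        return CommunityPartition(assignment, float("nan"), len(assignment))
    st = _State(G, seed)
    L_cur = st.L()
    for _ in range(max_passes):
        improved = False
        # node sweep
        order = st.rng.permutation(len(st.nodes))
        for i in order:
            n = st.nodes[i]
            w_to = st.node_comm_weight(n)
            src = int(st.comm[i])
            best_c, best_L = src, L_cur
            for c in sorted(w_to):
                if c == src:
                    continue
                st.move(i, c, w_to)
                L_new = st.L()
                st.move(i, src, w_to)
                if L_new < best_L - 1e-12:
                    best_c, best_L = c, L_new
            if best_c != src:
                st.move(i, best_c, w_to)
                L_cur = best_L
                improved = True
        # merge sweep over connected community pairs
        merged = True
        while merged:
            merged = False
            inter: dict[tuple[int, int], float] = {}
            for u, v, dd in G.edges(data=True):
                cu, cv = int(st.comm[st.idx[u]]), int(st.comm[st.idx[v]])
                if cu != cv:
                    key = (min(cu, cv), max(cu, cv))
                    inter[key] = inter.get(key, 0.0) + dd.get("weight", 1.0) / st.W2
            best = None
            used = np.unique(st.comm)
            pos = {int(c): j for j, c in enumerate(used)}
            for (c1, c2), w12 in sorted(inter.items()):
                q_new = np.delete(st.q[used], [pos[c1], pos[c2]])
                S_new = np.delete(st.S[used], [pos[c1], pos[c2]])
                q_new = np.append(q_new, st.q[c1] + st.q[c2] - 2.0 * w12)
                S_new = np.append(S_new, st.S[c1] + st.S[c2])
                L_new = st._L_of(q_new, S_new)
                if best is None or L_new < best[0]:
                    best = (L_new, c1, c2, w12)
            if best is not None and best[0] < L_cur - 1e-12:
                L_new, c1, c2, w12 = best
                st.q[c1] = st.q[c1] + st.q[c2] - 2.0 * w12
                st.S[c1] += st.S[c2]
                st.q[c2] = 0.0
                st.S[c2] = 0.0
                st.comm[st.comm == c2] = c1
                L_cur = L_new
                improved = True
                merged = True
        if not improved:
            break
    # contiguous ids, ordered by smallest member node id for determinism
    groups: dict[int, list[str]] = {}
    for n, c in zip(st.nodes, st.comm):
        groups.setdefault(int(c), []).append(n)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    assignment = {n: i for i, g in enumerate(ordered) for n in g}
    L_final = map_equation(G, assignment)
    return CommunityPartition(assignment, L_final, len(ordered))


def community_features(
    G: nx.Graph,
    partition: CommunityPartition,
    provider_attrs: pd.DataFrame | None,
    strengths: dict[str, float],
) -> pd.DataFrame:
    """Per-community feature table.

    Structural features come from the induced subgraph; the geometric mean
    of strength mu_G(s) uses full-network strengths, over all members and
    over in-prefecture members only.  Singleton communities report NaN
    distance and assortativity.
    """
    attrs = (provider_attrs.set_index("provider_id")
             if provider_attrs is not None else None)
    areas = (sorted(provider_attrs["area"].unique())
             if attrs is not None and "area" in attrs.columns else [])
    rows = []
    groups: dict[int, list[str]] = {}
    for n, c in partition.assignment.items():
        groups.setdefault(c, []).append(n)
    for c in sorted(groups, key=lambda c: -len(groups[c])):
        members = groups[c]
        sub = G.subgraph(members)
        if len(members) > 1 and sub.number_of_edges() > 0:
            feats = network_features(sub)
        else:
            feats = {"n_edges": 0, "avg_degree": 0.0, "avg_strength": 0.0,
                     "avg_distance": float("nan"),
                     "avg_clustering": float("nan") if len(members) == 1 else 0.0,
                     "assortativity": float("nan")}
        row = {
            "community": c,
            "n_nodes": len(members),
            "n_edges": feats["n_edges"],
            "avg_degree": feats["avg_degree"],
            "avg_strength": feats["avg_strength"],
            "avg_distance": feats["avg_distance"],
            "avg_clustering": feats["avg_clustering"],
            "assortativity": feats["assortativity"],
            "mu_g_s": geometric_mean_strength(members, strengths),
        }
        if attrs is not None:
            in_pref = [m for m in members
                       if bool(attrs.loc[m, "in_prefecture"])] if "in_prefecture" in attrs.columns else members
            row["n_in_prefecture"] = len(in_pref)
            row["mu_g_s_in_prefecture"] = (
                geometric_mean_strength(in_pref, strengths) if in_pref else float("nan")
            )
            for a in areas:
                row[f"n_area_{a}"] = sum(
                    1 for m in members if attrs.loc[m, "area"] == a
                )
        rows.append(row)
    return pd.DataFrame(rows)


def structure_vs_cooperation(table: pd.DataFrame) -> pd.DataFrame:
    """Linear relation of mu_G(s) to structure across communities.

    For each of: average distance normalized by community size, average
    clustering, and assortativity — OLS slope/intercept and the Pearson
    correlation against mu_G(s)."""
    if len(table) < 3:
        raise ValueError("need at least 3 communities")
    t = table.copy()
    t["d_over_n"] = t["avg_distance"] / t["n_nodes"]
    rows = []
    for feat in ("d_over_n", "avg_clustering", "assortativity"):
        sub = t[["mu_g_s", feat]].dropna()
        if len(sub) < 3:
            rows.append({"feature": feat, "slope": float("nan"),
                         "intercept": float("nan"), "pearson_r": float("nan"),
                         "n": len(sub)})
            continue
        res = stats.linregress(sub[feat], sub["mu_g_s"])
        rows.append({"feature": feat, "slope": float(res.slope),
                     "intercept": float(res.intercept),
                     "pearson_r": float(res.rvalue), "n": len(sub)})
    return pd.DataFrame(rows)
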