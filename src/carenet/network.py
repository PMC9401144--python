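"""Cosine-projected provider network and its structural features.

A patient x provider usage matrix B (B[i, j] = 1 iff patient j has at least
one claim at provider i, regardless of multiplicity) is projected onto a
weighted undirected provider graph whose edge weights are the cosine
similarities of the providers' patient vectors.  Cosine, rather than raw
shared-patient counts, normalizes away provider size: duplicating a
provider's patients cannot push a weight above 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteIncidence",
    "build_bipartite",
    "project_cosine",
    "giant_component",
    "network_features",
    "strengths",
    "ccdf",
]


@dataclass
class BipartiteIncidence:
    """0/1 incidence of provider usage. Rows are providers, columns patients
    (the provider-indexed reading, the one consistent with the cosine
    projection)."""

    B: sp.csr_matrix
    provider_index: list[str]
    patient_index: list[str]


def build_bipartite(
    claims: pd.DataFrame, record_types: tuple[str, ...] = ("inpatient", "outpatient")
) -> BipartiteIncidence:
    """Build B from claims; both inpatient and outpatient rows contribute by
    default (restrict via ``record_types`` for sensitivity runs)."""
    sub = claims[claims["record_type"].isin(record_types)]
    if len(sub) == 0:
        raise ValueError("no claims of the requested record types")
    providers = sorted(sub["provider_id"].unique())
    patients = sorted(sub["patient_id"].unique())
    p_idx = {p: i for i, p in enumerate(providers)}
    q_idx = {p: i for i, p in enumerate(patients)}
    rows = sub["provider_id"].map(p_idx).to_numpy()
    cols = sub["patient_id"].map(q_idx).to_numpy()
    data = np.ones(len(sub))
    B = sp.csr_matrix((data, (rows, cols)), shape=(len(providers), len(patients)))
    B.data[:] = 1.0  # multiplicity collapses to 0/1
    B.sum_duplicates()
    B.data[:] = 1.0
    return BipartiteIncidence(B=B, provider_index=providers, patient_index=patients)


def project_cosine(
    bip: BipartiteIncidence, provider_attrs: pd.DataFrame | None = None
) -> nx.Graph:
    """Project B onto the provider graph with cosine weights, self-loops
    removed and zero-weight edges never materialized."""
    B = bip.B.astype(float)
    deg = np.asarray(B.sum(axis=1)).ravel()
    keep = deg > 0
    if not keep.all():
        dropped = [p for p, k in zip(bip.provider_index, keep) if not k]
        logger.warning("excluding %d providers with zero patients: %s",
                       len(dropped), dropped[:5])
    providers = [p for p, k in zip(bip.provider_index, keep) if k]
    B = B[keep]
    norm = np.sqrt(np.asarray(B.multiply(B).sum(axis=1)).ravel())
    S = (B @ B.T).tocoo()
    G = nx.Graph()
    G.add_nodes_from(providers)
    for i, j, v in zip(S.row, S.col, S.data):
        if i < j and v > 0:
            G.add_edge(providers[i], providers[j], weight=float(v / (norm[i] * norm[j])))
    if provider_attrs is not None:
        cols = [c for c in ("area", "beds", "in_prefecture", "role")
                if c in provider_attrs.columns]
        attrs = provider_attrs.set_index("provider_id")[cols]
        for node in G.nodes:
            if node in attrs.index:
                G.nodes[node].update(attrs.loc[node].to_dict())
    return G


def giant_component(G: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component; size ties are
    broken toward the component containing the smallest node id."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    return G.subgraph(comps[0]).copy()


def strengths(G: nx.Graph) -> dict[str, float]:
    """Node strength: sum of incident edge weights."""
    return {n: float(d) for n, d in G.degree(weight="weight")}


def network_features(G: nx.Graph) -> dict:
    """Structural summary of the (assumed connected) provider network.

    Average distance uses unweighted shortest paths over ordered pairs;
    clustering is the unweighted local coefficient (0 for degree < 2);
    assortativity is the degree-degree Pearson correlation over edge
    endpoints in both orientations (NaN, with a warning, on degree-regular
    graphs where it is undefined).
    """
    N = G.number_of_nodes()
    L = G.number_of_edges()
    if N == 0:
        raise ValueError("empty network")
    degs = dict(G.degree())
    strs = strengths(G)
    if nx.is_connected(G):
        avg_d = nx.average_shortest_path_length(G) if N > 1 else float("nan")
    else:
        logger.warning("network is disconnected; averaging distance per component")
        comps = [G.subgraph(c) for c in nx.connected_components(G)]
        parts = [nx.average_shortest_path_length(c) for c in comps if len(c) > 1]
        avg_d = float(np.mean(parts)) if parts else float("nan")
    deg_vals = np.array(list(degs.values()), dtype=float)
    if L == 0 or deg_vals.std() == 0:
        r = float("nan")
        if L > 0:
            warnings.warn("assortativity undefined on a degree-regular graph")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(nx.degree_assortativity_coefficient(G))
    return {
        "n_nodes": N,
        "n_edges": L,
        "avg_degree": 2.0 * L / N,
        "avg_strength": float(np.mean(list(strs.values()))),
        "avg_distance": float(avg_d),
        "avg_clustering": float(nx.average_clustering(G)) if N > 0 else float("nan"),
        "assortativity": r,
        "degree": {n: int(k) for n, k in degs.items()},
        "strength": strs,
    }


def ccdf(values) -> pd.DataFrame:
    """Empirical complementary CDF: fraction of values >= x at each unique x."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("ccdf of empty sample")
    uniq = np.unique(v)
    frac = np.array([(v >= x).mean() for x in uniq])
    return pd.DataFrame({"value": uniq, "ccdf": frac})
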