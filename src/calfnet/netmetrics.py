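"""Individual network metrics, max-possible normalization, cohort standardization.

Five node-level metrics are computed on each weighted infancy network: binary
degree (number of associates), strength (summed HWI weights), weighted
betweenness (shortest paths through the node with edge length 1/weight, so
stronger association means shorter distance), eigenvector centrality
(principal eigenvector of the weighted adjacency matrix), and the binary
local clustering coefficient.  To compare networks of different sizes each
metric is normalized by the maximum value possible for a node in a network of
that size; across the subject cohort the normalized metrics are standardized
to SD units for modelling.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("calfnet")

METRIC_NAMES = ("degree", "strength", "betweenness", "eigenvector", "clustering")


def binary_degree(G: nx.Graph, node) -> int:
    """Number of individuals directly connected to ``node``."""
    if node not in G:
        raise ValueError(f"unknown node {node!r}")
    return G.degree(node)


def strength(G: nx.Graph, node) -> float:
    """Sum of HWI weights on ties incident to ``node`` (weighted degree)."""
    if node not in G:
        raise ValueError(f"unknown node {node!r}")
    return float(G.degree(node, weight="weight"))


def weighted_betweenness_all(G: nx.Graph) -> dict:
    """Unnormalized weighted betweenness for every node.

    Edge length is the reciprocal of the association weight; tied shortest
    paths share credit fractionally (Brandes' algorithm via igraph's C
    implementation, which keeps cohorts of ~100-node networks cheap).
    """
    import igraph as ig

    nodes = list(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in G.edges]
    lengths = [1.0 / d["weight"] for _, _, d in G.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    vals = g.betweenness(weights=lengths) if edges else [0.0] * len(nodes)
    return dict(zip(nodes, (float(v) for v in vals)))


def weighted_betweenness(G: nx.Graph, node) -> float:
    if node not in G:
        raise ValueError(f"unknown node {node!r}")
    return weighted_betweenness_all(G)[node]


def adjacency_matrix(G: nx.Graph) -> tuple[list, np.ndarray]:
    """Node order and dense weighted adjacency matrix of a network."""
    nodes = list(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for a, b, w in G.edges(data="weight"):
        A[index[a], index[b]] = A[index[b], index[a]] = w
    return nodes, A


def _power_iteration(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    x = np.ones(A.shape[0])
    x /= np.linalg.norm(x)
    for _ in range(max_iter):
        y = A @ x + x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol * np.linalg.norm(y):
            return np.abs(y)
        x = y
    logger.warning("eigenvector power iteration hit max_iter=%d", max_iter)
    return np.abs(x)


def eigenvector_centrality(G: nx.Graph, tol: float = 1e-10, max_iter: int = 100000) -> dict:
    """Principal-eigenvector centrality of the weighted adjacency matrix.

    Power iteration from an all-ones start (deterministic, no RNG) on the
    shifted matrix A + I; the unit shift leaves eigenvectors unchanged while
    breaking the +/- eigenvalue symmetry of bipartite graphs that would
    otherwise make plain power iteration oscillate.  Entries are nonnegative
    and returned on the unit-norm scale.  On a disconnected network mass
    concentrates on the dominant component; other components come out near 0.
    """
    if G.number_of_edges() == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless network")
    nodes, A = adjacency_matrix(G)
    return dict(zip(nodes, _power_iteration(A, tol, max_iter)))


def clustering_coefficient(G: nx.Graph, node, weighted: bool = False) -> float:
    """Local clustering of ``node``.

    Default is the binary (topological) coefficient: the fraction of
    neighbor pairs that are themselves connected, 0 when degree < 2.  With
    ``weighted=True`` the geometric-mean weighted variant is used instead.
    """
    if node not in G:
        raise ValueError(f"unknown node {node!r}")
    return float(nx.clustering(G, node, weight="weight" if weighted else None))


def compute_raw_metrics(G: nx.Graph, node, _cache: dict | None = None) -> dict:
    """All five raw metrics for one node; pass a dict to reuse whole-network work."""
    cache = _cache if _cache is not None else {}
    if "betweenness" not in cache:
        cache["betweenness"] = weighted_betweenness_all(G)
    if "eigenvector" not in cache:
        cache["eigenvector"] = (eigenvector_centrality(G)
                                if G.number_of_edges() else {n: 0.0 for n in G})
    return {
        "degree": binary_degree(G, node),
        "strength": strength(G, node),
        "betweenness": cache["betweenness"][node],
        "eigenvector": cache["eigenvector"][node],
        "clustering": clustering_coefficient(G, node),
    }


def normalize_metrics(G: nx.Graph, raw: dict, _cache: dict | None = None) -> dict:
    """Scale raw metrics by the maximum possible for a node in this network.

    degree and strength divide by n-1 (every possible tie, at HWI = 1 for
    strength); betweenness by (n-1)(n-2)/2 (all pairs routed through the
    node); eigenvector by the network's maximum component (so the most
    central node scores exactly 1); clustering is already in [0, 1].
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("normalization needs at least 2 nodes")
    cache = _cache if _cache is not None else {}
    if "eigenvector" not in cache:
        cache["eigenvector"] = (eigenvector_centrality(G)
                                if G.number_of_edges() else {v: 0.0 for v in G})
    ev_max = max(cache["eigenvector"].values())
    bet_max = (n - 1) * (n - 2) / 2.0
    return {
        "degree": raw["degree"] / (n - 1),
        "strength": raw["strength"] / (n - 1),
        "betweenness": (raw["betweenness"] / bet_max) if bet_max > 0 else 0.0,
        "eigenvector": (raw["eigenvector"] / ev_max) if ev_max > 0 else 0.0,
        "clustering": raw["clustering"],
    }


def eigenvector_excluding_mother(G: nx.Graph, subject, mother_id) -> tuple[float, bool]:
    """Subject's normalized eigenvector centrality with the maternal tie removed.

    The subject-mother *edge* is dropped (the mother node stays).  Returns
    ``(value, mother_edge_removed)``; if the mother is absent from the
    network, or not tied to the subject, the unmodified value is returned
    with flag False.  A subject isolated by the removal scores 0.
    """
    if mother_id is None or not G.has_edge(subject, mother_id):
        cache: dict = {}
        val = normalize_metrics(G, compute_raw_metrics(G, subject, cache), cache)
        return val["eigenvector"], False
    if G.degree(subject) == 1 or G.number_of_edges() == 1:
        return 0.0, True
    nodes, A = adjacency_matrix(G)
    i, j = nodes.index(subject), nodes.index(mother_id)
    A[i, j] = A[j, i] = 0.0
    ev = _power_iteration(A, tol=1e-10, max_iter=100000)
    ev_max = ev.max()
    return (float(ev[i]) / ev_max) if ev_max > 0 else 0.0, True


def metrics_table(networks: dict, individuals: pd.DataFrame,
                  subjects: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per subject: raw and normalized metrics plus metadata.

    ``networks`` maps subject id -> infancy network.  When a ``subjects``
    frame (from subject selection) is given, its sex/survival columns are
    carried through; the maternal-exclusion eigenvector variant is included
    whenever the mother id is known.
    """
    rows = []
    for subject, G in networks.items():
        cache: dict = {}
        raw = compute_raw_metrics(G, subject, cache)
        norm = normalize_metrics(G, raw, cache)
        mother = None
        if subject in individuals.index:
            m = individuals.loc[subject, "mother_id"]
            mother = None if pd.isna(m) else m
        if mother is None or not G.has_edge(subject, mother):
            ev_excl, removed = norm["eigenvector"], False
        else:
            ev_excl, removed = eigenvector_excluding_mother(G, subject, mother)
        row = {"subject_id": subject, "n_nodes": G.number_of_nodes()}
        row.update({f"raw_{k}": v for k, v in raw.items()})
        row.update({f"norm_{k}": v for k, v in norm.items()})
        row["eigenvector_excl_mother"] = ev_excl
        row["mother_edge_removed"] = removed
        if subjects is not None and subject in subjects.index:
            row["sex"] = subjects.loc[subject, "sex"]
            row["survived"] = bool(subjects.loc[subject, "survived"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def standardize_cohort(table: pd.DataFrame, columns=None, prefix: str = "std_") -> pd.DataFrame:
    """Z-score the given columns across subjects (sample SD), adding ``std_*`` columns.

    A zero-variance column cannot be standardized and raises a ``ValueError``
    naming it.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if c.startswith("norm_")]
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 subjects")
    for col in columns:
        vals = table[col].astype(float)
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance column {col!r} cannot be standardized")
        name = prefix + (col[len("norm_"):] if col.startswith("norm_") else col)
        out[name] = (vals - vals.mean()) / sd
    return out
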