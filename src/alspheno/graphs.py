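"""Graph-theory metrics of weighted structural connectivity matrices.

Each subject contributes one symmetric nonnegative matrix per diffusion
weighting (FA, AD, RD, MD).  From each matrix this module computes the
metric set used in whole-brain white-matter network analysis:
degree/density, weighted clustering (Onnela geometric-mean form) and
binary transitivity, shortest-path integration measures on the
reciprocal-weight length transform, betweenness, degree assortativity,
two modularity variants, and small-world indices normalized against
degree-preserving Maslov–Sneppen rewiring nulls.

Conventions (the source toolbox's internals are not published, so these
are fixed here and documented):

* distance between connected nodes = 1 / weight; weight 0 = no edge;
* characteristic path length averages over *connected* ordered pairs;
* global efficiency averages 1/d over all pairs with 1/inf = 0;
* degrees, transitivity and assortativity use the binarized graph;
* betweenness is unnormalized (counted over unordered pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from . import schema

__all__ = [
    "ConnectivityMatrix",
    "weights_to_lengths",
    "compute_degree_density",
    "compute_clustering_transitivity",
    "compute_path_efficiency",
    "compute_betweenness",
    "compute_assortativity",
    "compute_modularity",
    "rewire_preserving_degrees",
    "normalize_against_nulls",
    "compute_metric_set",
    "compute_graph_feature_block",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    weights: np.ndarray
    weighting: str = "FA"
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] < 3:
            raise ValueError("need at least 3 nodes")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.node_labels:
            self.node_labels = [f"n{i}" for i in range(w.shape[0])]
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binarized(self) -> np.ndarray:
        return self.weights > 0

    def to_networkx(self, length: bool = False) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            w = float(self.weights[i, j])
            if length:
                G.add_edge(i, j, weight=w, length=1.0 / w)
            else:
                G.add_edge(i, j, weight=w)
        return G


def weights_to_lengths(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Reciprocal-weight distance transform; absent edges become inf."""
    w = m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    lengths = np.full_like(w, np.inf, dtype=float)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def compute_degree_density(m: ConnectivityMatrix) -> tuple[float, float]:
    a = m.binarized()
    n = m.n_nodes
    degrees = a.sum(axis=1)
    n_edges = int(a.sum()) // 2
    density = 2.0 * n_edges / (n * (n - 1))
    return float(degrees.mean()), float(density)


def _onnela_clustering(weights: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering: geometric-mean triangle intensity."""
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(weights.shape[0])
    s = np.cbrt(weights / wmax)
    triangles = np.diagonal(s @ s @ s)  # sum over j,k of s_ij s_jk s_ki
    k = (weights > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def compute_clustering_transitivity(m: ConnectivityMatrix) -> tuple[float, float]:
    """Mean Onnela weighted clustering and binary transitivity.

    Weights are normalized by the matrix maximum, so a unit-weight graph
    reproduces the binary clustering coefficient exactly.  Transitivity
    is 3 x triangles / connected triplets on the binarized graph.
    """
    c = _onnela_clustering(m.weights)
    a = m.binarized().astype(float)
    triangles = np.trace(a @ a @ a)  # 6 x number of triangles
    k = a.sum(axis=1)
    triplets = (k * (k - 1)).sum()  # 2 x number of paths of length 2
    transitivity = float(triangles / triplets) if triplets > 0 else 0.0
    return float(c.mean()), transitivity


def _all_pairs_distances(m: ConnectivityMatrix) -> np.ndarray:
    lengths = weights_to_lengths(m)
    finite = np.where(np.isinf(lengths), 0.0, lengths)
    return _sp_shortest_path(finite, method="D", directed=False)


def _global_efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[np.isinf(dist[off])] = 0.0
    return float(inv.mean())


def compute_path_efficiency(m: ConnectivityMatrix) -> tuple[float, float, float]:
    """Characteristic path length, global efficiency, mean local efficiency."""
    dist = _all_pairs_distances(m)
    n = m.n_nodes
    off = ~np.eye(n, dtype=bool)
    connected = off & np.isfinite(dist)
    cpl = float(dist[connected].mean()) if connected.any() else np.inf
    geff = _global_efficiency(dist)

    a = m.binarized()
    local = []
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) < 2:
            local.append(0.0)
            continue
        sub = ConnectivityMatrix(m.weights[np.ix_(nbrs, nbrs)], m.weighting,
                                 [m.node_labels[j] for j in nbrs]) \
            if len(nbrs) >= 3 else None
        if sub is None:
            # two neighbours: efficiency is 1/d along their direct edge (if any)
            w = m.weights[nbrs[0], nbrs[1]]
            local.append(float(w) if w > 0 else 0.0)
        else:
            local.append(_global_efficiency(_all_pairs_distances(sub)))
    return cpl, geff, float(np.mean(local))


def compute_betweenness(m: ConnectivityMatrix) -> tuple[float, float]:
    """Mean nodal and mean edge betweenness (unnormalized, length-weighted).

    Shortest-path ties are split equally (Brandes accumulation); pairs
    are unordered.  The edge mean is over existing edges.
    """
    G = m.to_networkx(length=True)
    nodal = nx.betweenness_centrality(G, weight="length", normalized=False)
    mean_nodal = float(np.mean(list(nodal.values()))) if nodal else 0.0
    if G.number_of_edges() == 0:
        return mean_nodal, 0.0
    edge = nx.edge_betweenness_centrality(G, weight="length", normalized=False)
    return mean_nodal, float(np.mean(list(edge.values())))


def compute_assortativity(m: ConnectivityMatrix, weighted: bool = False) -> float:
    """Newman degree assortativity on the binarized graph.

    Pearson correlation of endpoint degrees over edges; undefined (NaN,
    with a warning) on degree-regular graphs where the endpoint-degree
    variance vanishes.  ``weighted=True`` correlates strengths using
    edge weights instead.
    """
    G = m.to_networkx()
    if G.number_of_edges() < 2:
        raise ValueError("assortativity needs at least 2 edges")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(
            G, weight="weight" if weighted else None)
    if not np.isfinite(r):
        warnings.warn("assortativity undefined: degree-regular graph",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(r)


def compute_modularity(m: ConnectivityMatrix, method: str = "louvain",
                       seed: int = 0) -> float:
    """Newman modularity Q of a community partition of the weighted graph.

    ``louvain`` runs seeded Louvain; ``greedy`` runs greedy (CNM)
    agglomeration, serving as the generic non-Louvain modularity entry.
    """
    G = m.to_networkx()
    if G.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    if method == "louvain":
        comms = nx.community.louvain_communities(G, weight="weight", seed=seed)
    elif method == "greedy":
        comms = nx.community.greedy_modularity_communities(G, weight="weight")
    else:
        raise ValueError(f"unknown modularity method {method!r}")
    return float(nx.community.modularity(G, comms, weight="weight"))


def rewire_preserving_degrees(m: ConnectivityMatrix, seed: int,
                              swaps_per_edge: int = 10) -> ConnectivityMatrix:
    """Maslov–Sneppen null: degree-preserving edge swaps carrying weights.

    Repeatedly picks two edges (a,b),(c,d) and rewires to (a,d),(c,b)
    when that creates neither self-loops nor duplicate edges; each edge's
    weight travels with its first endpoint.  The binary degree sequence
    is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    edges = [(int(i), int(j)) for i, j in zip(ii, jj)]
    wts = [float(m.weights[i, j]) for i, j in edges]
    n_edges = len(edges)
    if n_edges < 2:
        return ConnectivityMatrix(m.weights.copy(), m.weighting,
                                  list(m.node_labels))
    edge_set = set(edges)
    attempts = swaps_per_edge * n_edges
    for _ in range(attempts):
        e1, e2 = rng.choice(n_edges, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            b, a = a, b  # randomize which endpoint stays
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b or new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1], edges[e2] = new1, new2
    w = np.zeros_like(m.weights)
    for (i, j), wt in zip(edges, wts):
        w[i, j] = w[j, i] = wt
    return ConnectivityMatrix(w, m.weighting, list(m.node_labels))


def normalize_against_nulls(m: ConnectivityMatrix, n_nulls: int = 20,
                            seed: int = 0,
                            swaps_per_edge: int = 10) -> tuple[float, float, float]:
    """Small-world normalization: lambda = L/<L_null>, gamma = C/<C_null>,
    sigma = gamma/lambda, against a degree-preserving rewired ensemble."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    cpl, _, _ = compute_path_efficiency(m)
    c_obs, _ = compute_clustering_transitivity(m)
    rng = np.random.default_rng(seed)
    null_L, null_C = [], []
    for _ in range(n_nulls):
        null = rewire_preserving_degrees(m, int(rng.integers(2 ** 31)),
                                         swaps_per_edge)
        l_null, _, _ = compute_path_efficiency(null)
        c_null, _ = compute_clustering_transitivity(null)
        null_L.append(l_null)
        null_C.append(c_null)
    mean_L = float(np.mean(null_L))
    mean_C = float(np.mean(null_C))
    lam = cpl / mean_L if mean_L > 0 else np.nan
    gam = c_obs / mean_C if mean_C > 0 else np.nan
    sigma = gam / lam if np.isfinite(lam) and lam != 0 else np.nan
    return float(lam), float(gam), float(sigma)


def compute_metric_set(m: ConnectivityMatrix, seed: int = 0, n_nulls: int = 20,
                       include_mean_degree: bool = True) -> dict[str, float]:
    """All metrics for one matrix, keyed by the bare metric name."""
    mean_degree, density = compute_degree_density(m)
    mean_clust, transitivity = compute_clustering_transitivity(m)
    cpl, geff, leff = compute_path_efficiency(m)
    nodal_bw, edge_bw = compute_betweenness(m)
    assort = compute_assortativity(m)
    q_greedy = compute_modularity(m, "greedy", seed=seed)
    q_louvain = compute_modularity(m, "louvain", seed=seed)
    lam, gam, sigma = normalize_against_nulls(m, n_nulls=n_nulls, seed=seed)
    out = {
        "Assortativity": assort,
        "Density": density,
        "Mean_clustering_coefficient": mean_clust,
        "Transitivity": transitivity,
        "Global_efficiency": geff,
        "Mean_local_efficiency": leff,
        "Modularity": q_greedy,
        "Modularity_Louvian": q_louvain,
        "Characteristic_path_length": cpl,
        "Mean_nodal_betweenness": nodal_bw,
        "Mean_edge_betweenness": edge_bw,
        "Normalized path length": lam,
        "Normalized clustering": gam,
        "Small world index": sigma,
    }
    if include_mean_degree:
        out["Mean_degree"] = mean_degree
    return out


def compute_graph_feature_block(matrices: dict[str, ConnectivityMatrix],
                                seed: int = 0, n_nulls: int = 20,
                                include_mean_degree_ad: bool = False
                                ) -> dict[str, float]:
    """The 59 connectome features, in table order, from all four weightings.

    The printed schema omits Mean_degree for the AD weighting; pass
    ``include_mean_degree_ad=True`` to emit the completed 60-value block.
    """
    missing = [w for w in schema.GRAPH_WEIGHTINGS if w not in matrices]
    if missing:
        raise ValueError(f"missing weightings: {missing}")
    rng = np.random.default_rng(seed)
    per_weighting = {}
    for w in schema.GRAPH_WEIGHTINGS:
        per_weighting[w] = compute_metric_set(
            matrices[w], seed=int(rng.integers(2 ** 31)), n_nulls=n_nulls)
    block: dict[str, float] = {}
    for name in schema.graph_feature_names(include_mean_degree_ad):
        metric, weighting = name.rsplit("_", 1)
        block[name] = per_weighting[weighting][
            "Mean_degree" if metric == "Mean_degree" else metric]
    return block
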