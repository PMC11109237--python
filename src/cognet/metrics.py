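"""Node-level and global metrics of weighted networks.

Conventions (pinned — values of published tables depend on them):

- distances: edge length = 1 / weight; weighted shortest paths (Dijkstra);
  zero-weight edges are treated as absent for path finding;
- global efficiency: mean of inverse distances over distinct node pairs,
  disconnected pairs contributing 0;
- clustering: Onnela's weighted coefficient — weights normalized by the
  network maximum, triangle intensity the geometric mean of its three
  normalized weights; the global coefficient is the mean over nodes;
- local efficiency: the global efficiency of the subgraph induced on a
  node's neighbors (original weights), 0 for degree < 2;
- modularity: Newman's weighted Q for the best partition found by Louvain
  over seeded restarts; Q is always recomputed from the returned partition
  by the explicit formula, never trusted from the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .tmfg import WeightedNetwork


@dataclass
class GlobalMetrics:
    """The four global scalars plus the community partition behind Q."""

    global_clustering: float
    global_efficiency: float
    global_strength: float
    modularity_q: float
    partition: dict[str, int]

    def as_dict(self) -> dict[str, float]:
        return {
            "global_clustering": self.global_clustering,
            "global_efficiency": self.global_efficiency,
            "global_strength": self.global_strength,
            "modularity_q": self.modularity_q,
        }


GLOBAL_METRIC_NAMES = (
    "global_clustering",
    "global_efficiency",
    "global_strength",
    "modularity_q",
)
NODE_METRIC_NAMES = ("strength", "clustering", "local_efficiency")


def _as_matrix(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.weights
    return np.asarray(net, dtype=float)


def strength(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Per-node strength: sum of incident edge weights."""
    return _as_matrix(net).sum(axis=0)


def shortest_distances(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances with edge length 1/weight.

    Disconnected pairs are ``inf``; the diagonal is 0.
    """
    w = _as_matrix(net)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    n = w.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    finite = np.where(np.isinf(lengths), 0.0, lengths)
    d = _dijkstra(finite, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = np.where(d[iu] > 0, 1.0 / d[iu], 0.0)
    inv[np.isinf(d[iu])] = 0.0
    return float(inv.mean())


def global_efficiency(net: WeightedNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path distance over distinct node pairs."""
    return _efficiency_from_distances(shortest_distances(net))


def clustering(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    Weights are normalized by the graph maximum; C(v) is the sum over
    neighbor pairs of the cube-root triangle intensity, divided by
    k_v (k_v - 1).  Nodes with degree < 2 get 0.
    """
    w = _as_matrix(net)
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(w.shape[0])
    what = (w / wmax) ** (1.0 / 3.0)
    # diagonal of What^3 counts each triangle through v twice (both orders)
    cycles = np.diag(what @ what @ what)
    k = (w > 0).sum(axis=0)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cycles / denom, 0.0)
    return c


def local_efficiency(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Per-node local efficiency: global efficiency of the neighbor subgraph."""
    w = _as_matrix(net)
    n = w.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.nonzero(w[v] > 0)[0]
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        out[v] = _efficiency_from_distances(shortest_distances(sub))
    return out


def modularity_q(
    net: WeightedNetwork | np.ndarray, labels: np.ndarray
) -> float:
    """Newman's weighted modularity of a given partition.

    Q = (1/2m) * sum_ij (w_ij - s_i s_j / 2m) [c_i == c_j], with m the total
    edge weight and s the node strengths.
    """
    w = _as_matrix(net)
    labels = np.asarray(labels)
    s = w.sum(axis=0)
    two_m = s.sum()
    if two_m <= 0:
        return 0.0
    same = labels[:, None] == labels[None, :]
    return float(((w - np.outer(s, s) / two_m) * same).sum() / two_m)


def modularity(
    net: WeightedNetwork | np.ndarray,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Louvain community detection, best Q over seeded restarts.

    Returns (labels, Q) where Q is recomputed from the partition with
    :func:`modularity_q`.  Restart r uses RNG seed ``seed + r``, so the
    result is reproducible and the best of ``n_restarts`` independent runs.
    """
    w = _as_matrix(net)
    g = nx.from_numpy_array(w)
    # drop zero-weight structural edges: they carry no modularity mass
    g.remove_edges_from(
        [(u, v) for u, v, d in g.edges(data=True) if d.get("weight", 0) <= 0]
    )
    n = w.shape[0]
    best_labels = np.zeros(n, dtype=int)
    best_q = modularity_q(w, best_labels)
    for r in range(n_restarts):
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=int(seed) + r
        )
        labels = np.empty(n, dtype=int)
        for ci, members in enumerate(communities):
            for v in members:
                labels[v] = ci
        q = modularity_q(w, labels)
        if q > best_q:
            best_labels, best_q = labels, q
    return best_labels, best_q


def summarize(
    net: WeightedNetwork,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, GlobalMetrics]:
    """All node metrics and global metrics of a network.

    Returns a node table (strength, clustering, local_efficiency indexed by
    node name) and a :class:`GlobalMetrics` bundle with
    ``global_strength = sum of strengths = 2 x total edge weight``.
    """
    w = net.weights
    s = strength(w)
    c = clustering(w)
    le = local_efficiency(w)
    labels, q = modularity(w, n_restarts=n_restarts, seed=seed)
    node_table = pd.DataFrame(
        {"strength": s, "clustering": c, "local_efficiency": le},
        index=pd.Index(net.nodes, name="task"),
    )
    glob = GlobalMetrics(
        global_clustering=float(c.mean()),
        global_efficiency=global_efficiency(w),
        global_strength=float(s.sum()),
        modularity_q=q,
        partition={net.nodes[i]: int(labels[i]) for i in range(len(net.nodes))},
    )
    return node_table, glob


def metric_vector(
    w: np.ndarray,
    node_names: tuple[str, ...],
    n_restarts: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Flat {metric_name: value} map of every global and node metric.

    Node metrics are keyed ``strength[task]`` etc.  This is the bootstrap
    hot path; it works directly on the dense adjacency matrix.
    """
    s = w.sum(axis=0)
    c = clustering(w)
    le = local_efficiency(w)
    _, q = modularity(w, n_restarts=n_restarts, seed=seed)
    out = {
        "global_clustering": float(c.mean()),
        "global_efficiency": global_efficiency(w),
        "global_strength": float(s.sum()),
        "modularity_q": q,
    }
    for i, name in enumerate(node_names):
        out[f"strength[{name}]"] = float(s[i])
        out[f"clustering[{name}]"] = float(c[i])
        out[f"local_efficiency[{name}]"] = float(le[i])
    return out
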