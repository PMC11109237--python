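"""Triangulated maximally filtered graph (TMFG) on weighted task networks.

TMFG is a greedy planar filter for dense association matrices: it seeds the
maximum-weight tetrahedron, then repeatedly inserts the remaining vertex
that gains the most weight into one of the current triangular faces, each
insertion adding three edges and splitting one face into three.  The result
always has exactly 3n - 6 edges, is planar and chordal, and keeps the
original weights on the retained edges.

Conventions pinned here (variants in the literature differ):
- seed clique: exhaustive search over all C(n, 4) quadruples for the maximal
  sum of the 6 internal weights;
- tie-breaking: lexicographic — smallest vertex indices first, then face
  creation order — making the construction deterministic and permutation
  equivariant on generic (tie-free) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np


@dataclass
class WeightedNetwork:
    """An undirected weighted graph on named task nodes.

    ``weights`` is the dense symmetric adjacency matrix; node order follows
    ``nodes``.  ``edge_mask`` marks which pairs are structural edges — it
    defaults to ``weights > 0`` but may keep zero-weight edges, which a
    planar filter can legitimately retain (metric computations still treat
    zero weight as absent for paths and triangles).  ``domain_labels``
    optionally tags each node with a cognitive domain for reporting.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    domain_labels: dict[str, str] = field(default_factory=dict)
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {n} nodes"
            )
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if self.edge_mask is None:
            self.edge_mask = self.weights > 0
        else:
            self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
            if self.edge_mask.shape != (n, n):
                raise ValueError("edge_mask shape does not match nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.edge_mask, 1)))

    def edges(self) -> list[tuple[str, str, float]]:
        """(node_a, node_b, weight) triples in node order."""
        i, j = np.nonzero(np.triu(self.edge_mask, 1))
        return [
            (self.nodes[a], self.nodes[b], float(self.weights[a, b]))
            for a, b in zip(i, j)
        ]

    def total_weight(self) -> float:
        return float(np.triu(self.weights, 1).sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, name in enumerate(self.nodes):
            g.add_node(name, task=name, domain=self.domain_labels.get(name, ""))
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "WeightedNetwork":
        nodes = tuple(g.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for a, b, data in g.edges(data=True):
            w[index[a], index[b]] = w[index[b], index[a]] = data.get("weight", 1.0)
        mask = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for a, b in g.edges():
            mask[index[a], index[b]] = mask[index[b], index[a]] = True
        domains = {
            v: d for v, d in g.nodes(data="domain", default="") if d
        }
        return cls(nodes=nodes, weights=w, domain_labels=domains, edge_mask=mask)


def tmfg_adjacency(weights: np.ndarray) -> np.ndarray:
    """Greedy TMFG filter on a dense weight matrix; returns the filtered matrix.

    Zero-weight retained edges are indistinguishable from absent ones in the
    returned matrix; use :func:`tmfg` when the structural edge set matters.
    """
    return _tmfg_filter(weights)[0]


def _tmfg_filter(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """TMFG core: (filtered weight matrix, boolean edge mask).

    Raises on n < 4 or a non-symmetric input.  The diagonal is ignored.
    Zero weights are legal and can be retained — the 3n - 6 edge-count
    guarantee is structural, not weight-dependent.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError(f"weight matrix must be square, got {w.shape}")
    if n < 4:
        raise ValueError(f"TMFG requires at least 4 nodes, got {n}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative (use |rho|)")
    w = w.copy()
    np.fill_diagonal(w, 0.0)

    # seed: the quadruple with maximal internal weight, ties to the
    # lexicographically smallest quadruple (combinations yields them sorted)
    best_quad, best_sum = None, -np.inf
    for quad in combinations(range(n), 4):
        s = sum(w[a, b] for a, b in combinations(quad, 2))
        if s > best_sum:
            best_quad, best_sum = quad, s

    filtered = np.zeros_like(w)
    mask = np.zeros(w.shape, dtype=bool)
    for a, b in combinations(best_quad, 2):
        filtered[a, b] = filtered[b, a] = w[a, b]
        mask[a, b] = mask[b, a] = True

    faces = [frozenset(f) for f in combinations(best_quad, 3)]
    remaining = sorted(set(range(n)) - set(best_quad))

    while remaining:
        # best (vertex, face) pair by gain; ties resolved lexicographically
        # by vertex index then face creation order
        best = None  # (gain, vertex position, face position)
        for vi, v in enumerate(remaining):
            for fi, face in enumerate(faces):
                gain = sum(w[v, u] for u in face)
                if best is None or gain > best[0]:
                    best = (gain, vi, fi)
        _, vi, fi = best
        v = remaining.pop(vi)
        face = faces.pop(fi)
        for u in face:
            filtered[v, u] = filtered[u, v] = w[v, u]
            mask[v, u] = mask[u, v] = True
        for pair in combinations(sorted(face), 2):
            faces.append(frozenset((v, *pair)))
    return filtered, mask


def tmfg(
    weights: np.ndarray,
    nodes: tuple[str, ...] | None = None,
    domain_labels: dict[str, str] | None = None,
) -> WeightedNetwork:
    """TMFG filter returning a :class:`WeightedNetwork` on named nodes."""
    w = np.asarray(weights, dtype=float)
    if nodes is None:
        nodes = tuple(f"v{i}" for i in range(w.shape[0]))
    filtered, mask = _tmfg_filter(w)
    return WeightedNetwork(
        nodes=tuple(nodes),
        weights=filtered,
        domain_labels=dict(domain_labels or {}),
        edge_mask=mask,
    )


def planarity_check(net: WeightedNetwork | nx.Graph) -> bool:
    """True iff the graph is planar (left-right planarity test)."""
    g = net.to_networkx() if isinstance(net, WeightedNetwork) else net
    is_planar, _ = nx.check_planarity(g)
    return bool(is_planar)
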