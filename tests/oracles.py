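"""Independent brute-force oracles used to validate the main code paths.

Everything here is deliberately written without reusing the package's
implementations: distances by exhaustive simple-path enumeration, clustering
by a triple loop over the definition, the maximum-weight planar subgraph by
exhaustive edge-subset search, and TMFG by a literal step trace of the
insertion rule.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def brute_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path (length 1/weight) by simple-path enumeration."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)

    def explore(node, target, visited, dist):
        nonlocal best
        if dist >= best:
            return
        if node == target:
            best = dist
            return
        for nxt in range(n):
            if nxt not in visited and w[node, nxt] > 0:
                explore(nxt, target, visited | {nxt}, dist + 1.0 / w[node, nxt])

    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            explore(i, j, {i}, 0.0)
            d[i, j] = d[j, i] = best
    return d


def brute_efficiency(w: np.ndarray) -> float:
    """Mean inverse distance over distinct pairs, from brute distances."""
    d = brute_distances(w)
    n = w.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 0.0 if np.isinf(d[i, j]) or d[i, j] == 0 else 1.0 / d[i, j]
            count += 1
    return total / count


def brute_onnela_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by explicit triangle triple-loop."""
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    if wmax <= 0:
        return out
    for v in range(n):
        neighbors = [u for u in range(n) if w[v, u] > 0]
        k = len(neighbors)
        if k < 2:
            continue
        acc = 0.0
        for i, j in combinations(neighbors, 2):
            acc += 2.0 * ((w[v, i] / wmax) * (w[v, j] / wmax) * (w[i, j] / wmax)) ** (1 / 3)
        out[v] = acc / (k * (k - 1))
    return out


def brute_local_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if w[v, u] > 0]
        if len(nb) < 2:
            continue
        out[v] = brute_efficiency(w[np.ix_(nb, nb)])
    return out


def max_planar_weight(w: np.ndarray) -> float:
    """Maximum total weight over all planar spanning subgraphs with 3n-6 edges.

    Exhaustive over edge subsets; tractable for n <= 6 (C(15, 12) = 455).
    """
    n = w.shape[0]
    all_edges = list(combinations(range(n), 2))
    target = 3 * n - 6
    best = -np.inf
    for subset in combinations(all_edges, target):
        g = nx.Graph(subset)
        if g.number_of_nodes() < n:
            g.add_nodes_from(range(n))
        if nx.check_planarity(g)[0]:
            total = sum(w[a, b] for a, b in subset)
            best = max(best, total)
    return best


def tmfg_step_trace_5(w: np.ndarray) -> set[tuple[int, int]]:
    """Literal TMFG trace for n = 5: best K4 seed, then one insertion.

    Independent of the package's face bookkeeping — for five nodes the
    construction is: pick the quadruple with maximal internal weight, then
    connect the remaining vertex to the best of the four triangular faces.
    """
    assert w.shape == (5, 5)
    best_quad, best_sum = None, -np.inf
    for quad in combinations(range(5), 4):
        s = sum(w[a, b] for a, b in combinations(quad, 2))
        if s > best_sum:
            best_quad, best_sum = quad, s
    v = next(x for x in range(5) if x not in best_quad)
    best_face, best_gain = None, -np.inf
    for face in combinations(best_quad, 3):
        gain = sum(w[v, u] for u in face)
        if gain > best_gain:
            best_face, best_gain = face, gain
    edges = {tuple(sorted(e)) for e in combinations(best_quad, 2)}
    edges |= {tuple(sorted((v, u))) for u in best_face}
    return edges


def random_symmetric_weights(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    a = rng.uniform(0.01, 1.0, size=(n, n))
    w = (a + a.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
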