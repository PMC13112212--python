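"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — exhaustive path enumeration, direct
triple sums, power iteration, per-subset isomorphism tests — and shares no
code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/w by triple loop."""
    v = w.shape[0]
    d = np.full((v, v), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(v):
        for j in range(v):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(v):
        for i in range(v):
            for j in range(v):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(w: np.ndarray) -> float:
    d = floyd_warshall(w)
    v = w.shape[0]
    tot = 0.0
    for i in range(v):
        for j in range(v):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                tot += 1.0 / d[i, j]
    return tot / (v * (v - 1))


def nodal_efficiency(w: np.ndarray) -> np.ndarray:
    d = floyd_warshall(w)
    v = w.shape[0]
    out = np.zeros(v)
    for i in range(v):
        for j in range(v):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                out[i] += 1.0 / d[i, j]
    return out / (v - 1)


def onnela_clustering(w: np.ndarray) -> np.ndarray:
    """Direct triple sum of cube-rooted weight products (weights in [0,1])."""
    v = w.shape[0]
    out = np.zeros(v)
    for i in range(v):
        k = np.count_nonzero(w[i])
        if k < 2:
            continue
        s = 0.0
        for j in range(v):
            for h in range(v):
                if j != i and h != i and j != h:
                    s += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def betweenness(w: np.ndarray) -> np.ndarray:
    """Weighted betweenness by exhaustive simple-path enumeration.

    For every ordered pair (s, t) all simple paths are enumerated, shortest
    length (sum of 1/w) found, and each intermediate vertex of each shortest
    path credited with 1/count.  Normalised by (V−1)(V−2)/2 to match the
    undirected convention.
    """
    v = w.shape[0]
    acc = np.zeros(v)
    nodes = list(range(v))
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        rest = [x for x in nodes if x not in (s, t)]
        for k in range(len(rest) + 1):
            for mid in itertools.permutations(rest, k):
                seq = (s, *mid, t)
                ok = all(w[seq[i], seq[i + 1]] > 0 for i in range(len(seq) - 1))
                if ok:
                    length = sum(1.0 / w[seq[i], seq[i + 1]] for i in range(len(seq) - 1))
                    paths.append((length, seq))
        if not paths:
            continue
        best = min(p[0] for p in paths)
        shortest = [p[1] for p in paths if abs(p[0] - best) < 1e-12]
        for seq in shortest:
            for node in seq[1:-1]:
                acc[node] += 1.0 / len(shortest)
    norm = (v - 1) * (v - 2) / 2.0
    return acc / norm if norm > 0 else acc


def eigenvector_centrality(w: np.ndarray, iters: int = 20000, tol: float = 1e-14) -> np.ndarray:
    """Leading eigenvector by shifted power iteration, max-normalised.

    The shift w + σI (σ > max row sum) leaves eigenvectors unchanged but
    makes the Perron eigenvalue strictly dominant in magnitude, so the
    iteration also converges on bipartite graphs whose spectrum is
    symmetric (λ_max = −λ_min).
    """
    v = w.shape[0]
    if not np.any(w > 0):
        return np.zeros(v)
    shifted = w + (1.0 + w.sum(axis=1).max()) * np.eye(v)
    x = np.ones(v)
    for _ in range(iters):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return np.zeros(v)
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return x / x.max() if x.max() > 0 else x


def motif_census_iso(a: np.ndarray) -> dict[str, int]:
    """Motif census by per-subset isomorphism against reference graphs."""
    import networkx as nx

    refs3 = {
        "triangle": nx.complete_graph(3),
        "open_triad": nx.path_graph(3),
    }
    refs4 = {
        "square": nx.cycle_graph(4),
        "chain": nx.path_graph(4),
        "star": nx.star_graph(3),
        "clique": nx.complete_graph(4),
    }
    g = nx.from_numpy_array(a)
    v = a.shape[0]
    counts = {k: 0 for k in list(refs3) + list(refs4) + ["unclassified4"]}
    for sub in itertools.combinations(range(v), 3):
        sg = g.subgraph(sub)
        for name, ref in refs3.items():
            if nx.is_isomorphic(sg, ref):
                counts[name] += 1
                break
    for sub in itertools.combinations(range(v), 4):
        sg = g.subgraph(sub)
        matched = False
        for name, ref in refs4.items():
            if nx.is_isomorphic(sg, ref):
                counts[name] += 1
                matched = True
                break
        if not matched:
            counts["unclassified4"] += 1
    return counts


def bh_adjust(p: list[float]) -> list[float]:
    """Step-up BH adjustment by the textbook recipe."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def chi2_stat(table: np.ndarray) -> float:
    """Σ (O−E)²/E by direct loop."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def random_weighted_graph(v: int, p_edge: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric weight matrix with weights in (0, 1), zero diagonal."""
    w = np.zeros((v, v))
    for i in range(v):
        for j in range(i + 1, v):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.05, 0.95)
    return w
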