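"""Nodal and global weighted-graph metrics, Louvain modularity, participation.

Conventions follow the Brain Connectivity Toolbox forms used throughout
network neuroscience:

* clustering — Onnela weighted clustering on max-normalised weights,
  C_i = (1/(k_i(k_i−1))) Σ_{jh} (ŵ_ij ŵ_ih ŵ_jh)^{1/3};
* path lengths — Dijkstra on edge lengths 1/w; disconnected pairs have
  infinite distance and contribute zero to efficiency sums;
* betweenness — weighted shortest-path betweenness normalised by
  (V−1)(V−2)/2, so values lie in [0, 1];
* eigenvector centrality — leading eigenvector of the weight matrix,
  max-normalised to [0, 1];
* participation coefficient — degree-based, P_i = 1 − Σ_s (k_is/k_i)²
  (strength-based shares available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graph import BrainGraph

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "Partition",
    "ParticipationResult",
    "nodal_metrics",
    "global_metrics",
    "louvain_partition",
    "participation",
    "network_participation",
]


@dataclass
class NodalMetrics:
    """Per-node metrics of one subject's graph (arrays indexed like the graph)."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    eigenvector: np.ndarray

    def to_frame(self, parcel_ids: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel": parcel_ids,
                "degree": self.degree,
                "strength": self.strength,
                "clustering": self.clustering,
                "nodal_efficiency": self.nodal_efficiency,
                "betweenness": self.betweenness,
                "eigenvector": self.eigenvector,
            }
        )


@dataclass
class GlobalMetrics:
    """Whole-graph summaries; nodal quantities are averaged over vertices."""

    density: float
    mean_degree: float
    total_strength: float
    global_efficiency: float
    mean_clustering: float
    mean_betweenness: float
    mean_eigenvector: float


@dataclass
class Partition:
    """A Louvain module assignment with its modularity."""

    labels: np.ndarray  # module id per node
    q: float
    gamma: float
    seed: int
    n_restarts: int

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.tolist()))


@dataclass
class ParticipationResult:
    """Participation coefficient per node plus per-module degree shares."""

    p: np.ndarray
    module_degree: np.ndarray  # (n_nodes, n_modules) k_is
    module_ids: np.ndarray


def _distances(g: BrainGraph) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/w (inf if disconnected)."""
    w = g.w
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def nodal_metrics(g: BrainGraph) -> NodalMetrics:
    """Compute the six per-node metrics of one weighted graph."""
    v = g.n_vertices
    if v < 2:
        raise ValueError("metrics need at least two vertices")
    w = g.w
    a = (w > 0).astype(float)
    degree = a.sum(axis=1)
    strength = w.sum(axis=1)

    # Onnela clustering; weights are already in [0,1] by construction, so no
    # per-graph renormalisation is applied (a per-graph max would make the
    # coefficient incomparable across subjects with different peak weights)
    wmax = w.max()
    clustering = np.zeros(v)
    if wmax > 0:
        cube = np.cbrt(w / max(wmax, 1.0))
        cyc = np.diag(cube @ cube @ cube)
        denom = degree * (degree - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            clustering = np.where(denom > 0, cyc / denom, 0.0)

    d = _distances(g)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    nodal_eff = inv.sum(axis=1) / (v - 1)

    G = g.to_networkx()
    bt = nx.betweenness_centrality(G, weight="length", normalized=True)
    betweenness = np.array([bt[i] for i in range(v)])

    eigenvector = np.zeros(v)
    if g.n_edges > 0:
        vals, vecs = np.linalg.eigh(w)
        lead = np.abs(vecs[:, np.argmax(vals)])
        if lead.max() > 0:
            eigenvector = lead / lead.max()

    return NodalMetrics(
        degree=degree,
        strength=strength,
        clustering=clustering,
        nodal_efficiency=nodal_eff,
        betweenness=betweenness,
        eigenvector=eigenvector,
    )


def global_metrics(g: BrainGraph, nodal: NodalMetrics | None = None) -> GlobalMetrics:
    """Whole-graph metrics; ``nodal`` may be passed to avoid recomputation."""
    v = g.n_vertices
    if v < 2:
        raise ValueError("metrics need at least two vertices")
    if nodal is None:
        nodal = nodal_metrics(g)
    d = _distances(g)
    off = ~np.eye(v, dtype=bool)
    finite = off & np.isfinite(d)
    geff = float(np.sum(1.0 / d[finite]) / (v * (v - 1))) if finite.any() else 0.0
    return GlobalMetrics(
        density=2.0 * g.n_edges / (v * (v - 1)),
        mean_degree=float(nodal.degree.mean()),
        total_strength=float(np.triu(g.w, k=1).sum()),
        global_efficiency=geff,
        mean_clustering=float(nodal.clustering.mean()),
        mean_betweenness=float(nodal.betweenness.mean()),
        mean_eigenvector=float(nodal.eigenvector.mean()),
    )


def louvain_partition(
    g: BrainGraph, gamma: float = 1.0, seed: int = 0, n_restarts: int = 100
) -> Partition:
    """Best-of-``n_restarts`` Louvain partition of the weighted graph.

    Louvain is greedy and order-dependent; restarts are seeded
    deterministically from ``seed`` and the partition with the highest
    Newman modularity Q (at resolution ``gamma``) is returned, so repeated
    calls are identical.
    """
    if g.n_edges < 1:
        raise ValueError("cannot partition an empty graph")
    G = g.to_networkx()
    best_q = -np.inf
    best: list[set[int]] | None = None
    for k in range(n_restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=seed + k
        )
        q = nx.community.modularity(G, comms, weight="weight", resolution=gamma)
        if q > best_q + 1e-12:
            best_q, best = q, comms
    labels = np.empty(g.n_vertices, dtype=int)
    for m, comm in enumerate(sorted(best, key=min)):
        for node in comm:
            labels[node] = m
    return Partition(labels=labels, q=float(best_q), gamma=gamma, seed=seed, n_restarts=n_restarts)


def participation(
    g: BrainGraph, part: Partition, use_strength: bool = False
) -> ParticipationResult:
    """Participation coefficient P_i = 1 − Σ_s (k_is/k_i)² per node.

    ``k_is`` counts edges (or, with ``use_strength``, sums weights) from
    node i into module s.  Isolated nodes get P = 0.
    """
    labels = np.asarray(part.labels)
    if labels.shape[0] != g.n_vertices:
        raise ValueError("partition does not cover the graph")
    mods = np.unique(labels)
    m = (g.w > 0).astype(float) if not use_strength else g.w
    k = m.sum(axis=1)
    k_is = np.zeros((g.n_vertices, mods.size))
    for s, mod in enumerate(mods):
        k_is[:, s] = m[:, labels == mod].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(k[:, None] > 0, k_is / k[:, None], 0.0)
    p = np.where(k > 0, 1.0 - (shares**2).sum(axis=1), 0.0)
    return ParticipationResult(p=p, module_degree=k_is, module_ids=mods)


def network_participation(
    subject_tables: list[pd.DataFrame], presence_min: float = 0.2
) -> pd.DataFrame:
    """Per-subject mean participation per resting-state network.

    ``subject_tables`` holds one tidy frame per subject with columns
    ``subject``, ``group``, ``network``, ``participation`` (one row per
    included parcel).  Networks represented in fewer than ``presence_min``
    of subjects are dropped cohort-wide.  Returns a tidy frame with one row
    per subject × retained network.
    """
    if not subject_tables:
        raise ValueError("no subjects")
    n_subj = len(subject_tables)
    presence: dict[str, int] = {}
    for tab in subject_tables:
        for net in set(tab["network"]):
            presence[net] = presence.get(net, 0) + 1
    kept = {net for net, cnt in presence.items() if cnt / n_subj >= presence_min}

    rows = []
    for tab in subject_tables:
        sub = tab[tab["network"].isin(kept)]
        agg = sub.groupby("network", sort=True)["participation"].mean()
        for net, val in agg.items():
            rows.append(
                {
                    "subject": tab["subject"].iloc[0],
                    "group": tab["group"].iloc[0],
                    "network": net,
                    "participation": float(val),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "group", "network", "participation"])
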