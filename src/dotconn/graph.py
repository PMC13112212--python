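"""Weighted functional-connectivity graph construction.

Per subject: full-record Pearson correlation between parcel time series,
Fisher r-to-z variance stabilisation, absolute-r thresholding at 0.2
(inclusive — "spurious" means |r| < 0.2), and rescaling of |z| by 2.65 so
every retained weight stays below 1.  Edge signs are stored separately so
downstream metrics can operate on non-negative weights while the sign
convention stays auditable.

Sparsity follows the standard graph-density complement,
``sparsity = 1 − density = 1 − 2E / (V(V−1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .parcel import ParcelTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "BrainGraph",
    "GroupConnectome",
    "correlation_matrix",
    "build_graph",
    "sparsity",
    "density",
    "group_connectome",
]


@dataclass
class ConnectivityMatrix:
    """Pearson r and Fisher z matrices over a subject's included parcels."""

    r: np.ndarray
    z: np.ndarray
    parcel_ids: np.ndarray
    network_labels: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.r, self.r.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")

    @property
    def n_parcels(self) -> int:
        return self.r.shape[0]


@dataclass
class BrainGraph:
    """Thresholded weighted undirected graph (V vertices, E edges).

    ``w`` is the symmetric non-negative weight matrix with zero diagonal and
    all weights < 1; ``sign`` records the sign of the underlying correlation
    for every retained edge (0 where no edge).
    """

    w: np.ndarray
    sign: np.ndarray
    parcel_ids: np.ndarray
    network_labels: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(w < 0) or np.any(w >= 1):
            raise ValueError("weights must lie in [0, 1)")
        self.w = w

    @property
    def n_vertices(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.w, k=1)))

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency (edge present iff weight > 0)."""
        return (self.w > 0).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        ii, jj = np.nonzero(np.triu(self.w, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(i, j, weight=float(self.w[i, j]), length=1.0 / float(self.w[i, j]))
        return g


@dataclass
class GroupConnectome:
    """Edges surviving the group rule: present in enough subjects and non-zero on average."""

    edges: pd.DataFrame  # parcel_i, parcel_j, presence, p, mean_z, mean_w, retained
    presence_min: float
    alpha: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)


def correlation_matrix(pts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Full-record Pearson correlation between every pair of parcel series."""
    if pts.n_parcels < 2:
        raise ValueError("need at least two parcels")
    if pts.n_samples < 3:
        raise ValueError("need at least three samples")
    sds = pts.data.std(axis=0)
    if np.any(sds == 0):
        bad = pts.parcel_ids[sds == 0]
        raise ValueError(f"constant parcel series: {bad.tolist()}")
    r = np.corrcoef(pts.data.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = np.zeros_like(r)
    off = ~np.eye(r.shape[0], dtype=bool)
    z[off] = np.arctanh(np.clip(r[off], -0.9999999, 0.9999999))
    return ConnectivityMatrix(
        r=r, z=z, parcel_ids=pts.parcel_ids, network_labels=pts.network_labels
    )


def build_graph(
    cm: ConnectivityMatrix, r_thresh: float = 0.2, scale: float = 2.65
) -> BrainGraph:
    """Threshold at |r| ≥ ``r_thresh`` and weight retained edges by |z|/``scale``.

    The threshold is inclusive (an edge at exactly |r| = 0.2 is retained);
    weights at or above 1 — possible only for |r| ≳ 0.99 — raise rather than
    clip, with advice to enlarge the scale.
    """
    keep = (np.abs(cm.r) >= r_thresh) & ~np.eye(cm.n_parcels, dtype=bool)
    w = np.where(keep, np.abs(cm.z) / scale, 0.0)
    if np.any(w >= 1.0):
        raise ValueError(
            "a rescaled weight reached 1 (|r| ≥ ~0.99); increase the scale divisor"
        )
    sign = np.where(keep, np.sign(cm.r).astype(int), 0)
    return BrainGraph(
        w=w, sign=sign, parcel_ids=cm.parcel_ids, network_labels=cm.network_labels
    )


def density(g: BrainGraph) -> float:
    """Fraction of possible edges present, 2E / (V(V−1))."""
    v = g.n_vertices
    if v < 2:
        raise ValueError("density needs at least two vertices")
    return 2.0 * g.n_edges / (v * (v - 1))


def sparsity(g: BrainGraph) -> float:
    """1 − density; the complement of the fraction of possible edges present."""
    return 1.0 - density(g)


def group_connectome(
    cms: list[ConnectivityMatrix],
    presence_min: float = 0.2,
    alpha: float = 0.05,
    r_thresh: float = 0.2,
) -> GroupConnectome:
    """Edge-wise group connectome.

    An edge is retained iff it is present (post-threshold) in strictly more
    than ``presence_min`` of the group's subjects *and* a one-sample t-test
    of the subjects' Fisher z-values against zero is significant at
    ``alpha`` (uncorrected).  Edges observable in fewer than two subjects
    are excluded.
    """
    if len(cms) < 3:
        raise ValueError("group connectome needs at least three subjects")
    n_subj = len(cms)
    all_ids = sorted({int(p) for cm in cms for p in cm.parcel_ids})
    index = {p: k for k, p in enumerate(all_ids)}
    P = len(all_ids)
    present = np.zeros((P, P), dtype=int)
    zsums: list[list[list[float]]] = [[[] for _ in range(P)] for _ in range(P)]
    for cm in cms:
        loc = np.array([index[int(p)] for p in cm.parcel_ids])
        for a in range(cm.n_parcels):
            for b in range(a + 1, cm.n_parcels):
                i, j = loc[a], loc[b]
                i, j = min(i, j), max(i, j)
                zsums[i][j].append(float(cm.z[a, b]))
                if abs(cm.r[a, b]) >= r_thresh:
                    present[i, j] += 1

    rows = []
    for i in range(P):
        for j in range(i + 1, P):
            zs = np.array(zsums[i][j])
            if zs.size < 2:
                continue
            frac = present[i, j] / n_subj
            if np.allclose(zs, zs[0]):
                # degenerate: identical values; significant iff non-zero
                p = 0.0 if zs[0] != 0 else 1.0
            else:
                p = float(sps.ttest_1samp(zs, 0.0).pvalue)
            retained = (frac > presence_min) and (p < alpha)
            rows.append(
                {
                    "parcel_i": all_ids[i],
                    "parcel_j": all_ids[j],
                    "presence": frac,
                    "p": p,
                    "mean_z": float(zs.mean()),
                    "mean_w": float(np.abs(zs).mean() / 2.65),
                    "retained": retained,
                }
            )
    edges = pd.DataFrame(
        rows,
        columns=["parcel_i", "parcel_j", "presence", "p", "mean_z", "mean_w", "retained"],
    )
    return GroupConnectome(edges=edges, presence_min=presence_min, alpha=alpha)
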