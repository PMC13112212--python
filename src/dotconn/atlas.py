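"""Synthetic cortical parcellation atlases.

A parcellation atlas assigns every node of a (here synthetic) cortical mesh
to a parcel, and every parcel to a named resting-state network.  The real
analysis this package models uses a 400-parcel atlas with a 17-network
labelling; the synthetic atlas reproduces the structural features the
pipeline relies on — a node→parcel map, one network label per parcel and a
3-D centroid per parcel — at whatever granularity a test or simulation asks
for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticAtlas", "make_atlas"]


@dataclass(frozen=True)
class SyntheticAtlas:
    """A synthetic parcellation: nodes grouped into parcels, parcels into networks.

    Attributes
    ----------
    parcel_ids : (P,) int array of parcel identifiers.
    network_labels : (P,) array of network names, one per parcel.
    centroids : (P, 3) float array, parcel centroids in mm.
    node_to_parcel : (N,) int array mapping each mesh node to a parcel id.
    node_positions : (N, 3) float array, node coordinates in mm.
    """

    parcel_ids: np.ndarray
    network_labels: np.ndarray
    centroids: np.ndarray
    node_to_parcel: np.ndarray
    node_positions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != len(set(self.parcel_ids.tolist())):
            raise ValueError("parcel ids must be unique")
        if self.network_labels.shape[0] != self.n_parcels:
            raise ValueError("one network label per parcel required")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("parcel centroids must be finite")
        present = set(self.node_to_parcel.tolist())
        if not set(self.parcel_ids.tolist()) <= present:
            raise ValueError("every parcel must own at least one node")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_to_parcel)

    @property
    def networks(self) -> list[str]:
        """Unique network names in first-appearance order."""
        seen: dict[str, None] = {}
        for name in self.network_labels.tolist():
            seen.setdefault(name, None)
        return list(seen)

    def nodes_of(self, parcel_id: int) -> np.ndarray:
        """Indices of the mesh nodes belonging to ``parcel_id``."""
        return np.flatnonzero(self.node_to_parcel == parcel_id)

    def parcel_index(self, parcel_id: int) -> int:
        idx = np.flatnonzero(self.parcel_ids == parcel_id)
        if idx.size == 0:
            raise KeyError(f"unknown parcel id {parcel_id}")
        return int(idx[0])

    def network_of(self, parcel_id: int) -> str:
        return str(self.network_labels[self.parcel_index(parcel_id)])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n unit vectors roughly evenly spread on the sphere."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / max(n, 1)
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    theta = golden * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_atlas(
    n_parcels: int,
    n_networks: int,
    nodes_per_parcel: int = 5,
    seed: int = 0,
    network_radius_mm: float = 60.0,
    parcel_radius_mm: float = 20.0,
    parcel_jitter_mm: float = 2.0,
    node_jitter_mm: float = 3.0,
) -> SyntheticAtlas:
    """Build a synthetic atlas with near-even network membership.

    Parcels are partitioned into ``n_networks`` contiguous blocks whose sizes
    differ by at most one.  Networks are laid out as spatial clusters —
    network centres spread over a sphere of ``network_radius_mm``, parcels on
    a local sphere of ``parcel_radius_mm`` around their network centre — so
    parcels of one network are mutually closer than parcels of different
    networks, while distinct parcels keep a minimum spacing (optical channels
    cannot separate regions that overlap).  Deterministic for a fixed seed.
    """
    if n_parcels < 1 or n_networks < 1 or nodes_per_parcel < 1:
        raise ValueError("n_parcels, n_networks and nodes_per_parcel must be positive")
    if n_networks > n_parcels:
        raise ValueError(f"n_networks ({n_networks}) may not exceed n_parcels ({n_parcels})")

    rng = np.random.default_rng(seed)
    parcel_ids = np.arange(1, n_parcels + 1, dtype=int)

    # contiguous near-even blocks: first (n_parcels % n_networks) blocks get one extra
    base, extra = divmod(n_parcels, n_networks)
    labels = []
    for k in range(n_networks):
        size = base + (1 if k < extra else 0)
        labels.extend([f"Net{k + 1:02d}"] * size)
    network_labels = np.array(labels, dtype=object)

    net_centres = network_radius_mm * _fibonacci_sphere(n_networks)

    net_index = {f"Net{k + 1:02d}": k for k in range(n_networks)}
    centroids = np.empty((n_parcels, 3))
    counts = np.bincount([net_index[str(l)] for l in network_labels], minlength=n_networks)
    offsets = {k: parcel_radius_mm * _fibonacci_sphere(int(c)) for k, c in enumerate(counts)}
    slot = dict.fromkeys(range(n_networks), 0)
    for p in range(n_parcels):
        k = net_index[str(network_labels[p])]
        centroids[p] = (
            net_centres[k]
            + offsets[k][slot[k]]
            + rng.normal(scale=parcel_jitter_mm, size=3)
        )
        slot[k] += 1

    node_to_parcel = np.repeat(parcel_ids, nodes_per_parcel)
    node_positions = (
        np.repeat(centroids, nodes_per_parcel, axis=0)
        + rng.normal(scale=node_jitter_mm, size=(n_parcels * nodes_per_parcel, 3))
    )

    return SyntheticAtlas(
        parcel_ids=parcel_ids,
        network_labels=network_labels,
        centroids=centroids,
        node_to_parcel=node_to_parcel,
        node_positions=node_positions,
    )
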