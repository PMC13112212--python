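"""Induced-subgraph motif census and hub-frequency profiling.

Motifs are counted on the binarised graph (edge present iff weight > 0)
with *induced*-subgraph semantics: every node subset of size 3 or 4 is
classified into exactly one class by its induced edge pattern, so the
classes are disjoint and the natural normalisation is the number of
subsets, C(V,3) and C(V,4).

Three-node classes: triangle (3 edges), open triad (2-edge path).
Four-node classes: square (chordless 4-cycle), chain (path P4),
star (K1,3), clique (K4).  Four-node subsets matching none of these
(e.g. the diamond or the triangle-plus-pendant "paw") are reported as
``unclassified``.

Hubs: per subject and metric, the top ⌈10%·N⌉ parcels are flagged; a
parcel's hub frequency is how often it is flagged among the subjects that
include it.  Low-frequency parcels are removed in two stages (<15%, then a
20% retention floor) and an "overall centrality" aggregates the degree,
betweenness and eigenvector frequencies by their median.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .graph import BrainGraph

__all__ = [
    "MotifCensus",
    "HubProfile",
    "motif_census",
    "hub_frequencies",
    "filter_hubs",
    "HUB_METRICS",
    "CENTRALITY_METRICS",
]

MOTIFS_3 = ("triangle", "open_triad")
MOTIFS_4 = ("square", "chain", "star", "clique")
HUB_METRICS = (
    "participation",
    "degree",
    "betweenness",
    "eigenvector",
    "clustering",
    "nodal_efficiency",
)
CENTRALITY_METRICS = ("degree", "betweenness", "eigenvector")


@dataclass
class MotifCensus:
    """Raw counts and subset-normalised frequencies per motif class."""

    counts: dict[str, int]
    frequencies: dict[str, float]
    triangle_open_ratio: float | None  # None when there are no open triads

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [self.frequencies[m] for m in self.counts],
            }
        )


@dataclass
class HubProfile:
    """Per-parcel hub frequencies per metric, plus the aggregate centrality."""

    frequencies: pd.DataFrame  # index parcel, columns HUB_METRICS (+ n_subjects)
    group_size: int

    def overall_centrality(self) -> pd.Series:
        """Median of the degree, betweenness and eigenvector hub frequencies."""
        return self.frequencies[list(CENTRALITY_METRICS)].median(axis=1)


def _classify4(e: np.ndarray) -> np.ndarray:
    """Classify 4-node induced patterns from their six edge indicators.

    ``e`` is (n_subsets, 6) with columns for pairs (01,02,03,12,13,23).
    Returns an integer class per subset: 0 square, 1 chain, 2 star,
    3 clique, 4 unclassified.
    """
    e = e.astype(int)  # bool "+" would be logical OR, not a degree sum
    s = e.sum(axis=1)
    d0 = e[:, 0] + e[:, 1] + e[:, 2]
    d1 = e[:, 0] + e[:, 3] + e[:, 4]
    d2 = e[:, 1] + e[:, 3] + e[:, 5]
    d3 = e[:, 2] + e[:, 4] + e[:, 5]
    degs = np.stack([d0, d1, d2, d3], axis=1)
    dmax = degs.max(axis=1)
    dmin = degs.min(axis=1)

    out = np.full(e.shape[0], 4, dtype=int)
    out[s == 6] = 3  # clique K4
    out[(s == 4) & (dmax == 2)] = 0  # chordless 4-cycle
    out[(s == 3) & (dmax == 2) & (dmin == 1)] = 1  # path P4
    out[(s == 3) & (dmax == 3) & (dmin == 1)] = 2  # star K1,3
    return out


def motif_census(g: BrainGraph) -> MotifCensus:
    """Count 3- and 4-node induced motifs of the binarised graph.

    Counts are normalised by the number of node subsets of the motif's
    size; the triangle/open-triad ratio is ``None`` when no open triads
    exist.  Requires V ≥ 3 (V ≥ 4 for the four-node classes, which are
    otherwise reported as zero with zero denominator frequency).
    """
    v = g.n_vertices
    if v < 3:
        raise ValueError("motif census needs at least three vertices")
    a = g.w > 0

    counts: dict[str, int] = {m: 0 for m in MOTIFS_3 + MOTIFS_4}

    trips = np.array(list(itertools.combinations(range(v), 3)))
    e3 = np.stack(
        [
            a[trips[:, 0], trips[:, 1]],
            a[trips[:, 0], trips[:, 2]],
            a[trips[:, 1], trips[:, 2]],
        ],
        axis=1,
    )
    s3 = e3.sum(axis=1)
    counts["triangle"] = int(np.count_nonzero(s3 == 3))
    counts["open_triad"] = int(np.count_nonzero(s3 == 2))

    n4 = 0
    unclassified = 0
    if v >= 4:
        quads = np.array(list(itertools.combinations(range(v), 4)))
        pairs = list(itertools.combinations(range(4), 2))
        e4 = np.stack([a[quads[:, i], quads[:, j]] for i, j in pairs], axis=1)
        cls = _classify4(e4)
        for k, name in enumerate(MOTIFS_4):
            counts[name] = int(np.count_nonzero(cls == k))
        unclassified = int(np.count_nonzero(cls == 4))
        n4 = comb(v, 4)
    counts["unclassified4"] = unclassified

    n3 = comb(v, 3)
    freqs = {m: counts[m] / n3 for m in MOTIFS_3}
    freqs.update({m: (counts[m] / n4 if n4 else 0.0) for m in MOTIFS_4})
    freqs["unclassified4"] = counts["unclassified4"] / n4 if n4 else 0.0

    ratio = (
        counts["triangle"] / counts["open_triad"] if counts["open_triad"] > 0 else None
    )
    return MotifCensus(counts=counts, frequencies=freqs, triangle_open_ratio=ratio)


def hub_frequencies(nodal_table: pd.DataFrame, top_fraction: float = 0.10) -> HubProfile:
    """Hub frequency per parcel per metric over one group's subjects.

    ``nodal_table`` is tidy with columns ``subject``, ``parcel`` and one
    column per metric in :data:`HUB_METRICS` (missing metric columns are
    skipped).  Per subject and metric the top ⌈top_fraction·N⌉ parcels are
    flagged, ties broken by metric value then smallest parcel id; a
    parcel's frequency is (times flagged) / (subjects including it).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    metrics = [m for m in HUB_METRICS if m in nodal_table.columns]
    if not metrics:
        raise ValueError("no recognised metric columns")
    subjects = sorted(nodal_table["subject"].unique().tolist())
    parcels = sorted(nodal_table["parcel"].unique().tolist())
    flagged = {m: {p: 0 for p in parcels} for m in metrics}
    included = {p: 0 for p in parcels}

    for subj in subjects:
        tab = nodal_table[nodal_table["subject"] == subj]
        n = len(tab)
        n_top = int(np.ceil(top_fraction * n))
        for p in tab["parcel"]:
            included[p] += 1
        for m in metrics:
            order = tab.sort_values([m, "parcel"], ascending=[False, True])
            for p in order["parcel"].iloc[:n_top]:
                flagged[m][p] += 1

    data = {
        m: [flagged[m][p] / included[p] if included[p] else 0.0 for p in parcels]
        for m in metrics
    }
    freq = pd.DataFrame(data, index=pd.Index(parcels, name="parcel"))
    freq["n_subjects"] = [included[p] for p in parcels]
    return HubProfile(frequencies=freq, group_size=len(subjects))


def filter_hubs(
    profile: HubProfile, remove_below: float = 0.15, retain_at: float = 0.20
) -> tuple[HubProfile, dict]:
    """Two-stage hub filter and group summary.

    Stage 1 removes parcels never reaching ``remove_below`` frequency on any
    metric; stage 2 keeps only parcels that are hubs (frequency ≥
    ``retain_at``) for at least one metric.  Overall centrality (median of
    the degree/betweenness/eigenvector frequencies) is recomputed on the
    survivors; the summary reports the hub count and the median [IQR] of
    overall centrality.
    """
    freq = profile.frequencies
    metrics = [m for m in HUB_METRICS if m in freq.columns]
    fmax = freq[metrics].max(axis=1)
    kept = freq[(fmax >= remove_below) & (fmax >= retain_at)]
    retained = HubProfile(frequencies=kept, group_size=profile.group_size)
    centrality = retained.overall_centrality()
    if len(centrality):
        q1, med, q3 = np.percentile(centrality, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    summary = {
        "hub_count": int(len(kept)),
        "median_overall_centrality": float(med),
        "iqr_overall_centrality": [float(q1), float(q3)],
    }
    return retained, summary
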