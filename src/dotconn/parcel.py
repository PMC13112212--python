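"""From channel space to parcel time series.

The full imaging chain would reconstruct channel data into a cortical image
via a photon-transport forward model; this package consumes the forward
model's *sensitivity* (Jacobian) matrix instead and implements everything
downstream of it: which mesh nodes a subject's good channels can actually
see, which atlas parcels have enough sensitive nodes to be trusted, the
two-wavelength linear inversion to chromophore concentrations, the
node→parcel averaging, and global-signal handling.

Only ΔHbO propagates into connectivity analysis; ΔHbR is computed and
returned for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .atlas import SyntheticAtlas
from .qc import ChannelMask, ODTimeSeries

__all__ = [
    "SensitivityMatrix",
    "ChromophoreModel",
    "ParcelTimeSeries",
    "sensitive_nodes",
    "include_parcels",
    "mbll_invert",
    "channel_to_nodes",
    "parcel_average",
    "global_signal_regress",
    "global_coupling",
]


@dataclass
class SensitivityMatrix:
    """Per-wavelength channel×node sensitivities (non-negative Jacobian).

    ``j`` has shape (n_wavelengths, n_channels, n_nodes).  Rows are
    normalised by their channel-wise maximum wherever a relative sensitivity
    is needed.
    """

    j: np.ndarray

    def __post_init__(self) -> None:
        self.j = np.asarray(self.j, dtype=float)
        if self.j.ndim != 3:
            raise ValueError("sensitivity must be (wavelengths, channels, nodes)")
        if not np.all(np.isfinite(self.j)) or np.any(self.j < 0):
            raise ValueError("sensitivities must be finite and non-negative")

    @property
    def n_channels(self) -> int:
        return self.j.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.j.shape[2]

    def normalised(self) -> np.ndarray:
        """Row-normalised sensitivities (each channel's max maps to 1)."""
        row_max = self.j.max(axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            jn = self.j / row_max
        return np.where(row_max > 0, jn, 0.0)


@dataclass
class ChromophoreModel:
    """2×2 extinction-coefficient matrix ε (wavelength × chromophore).

    Columns are (HbO, HbR); units 1/(mM·mm).  Must be invertible so the
    modified Beer–Lambert system Δμa = ε·ΔC has a unique solution.
    """

    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (2, 2):
            raise ValueError("epsilon must be 2×2 (wavelength × chromophore)")

    @property
    def invertible(self) -> bool:
        return abs(np.linalg.det(self.epsilon)) > 1e-12 * np.abs(self.epsilon).max() ** 2


# extinction coefficients in the spirit of 735/850 nm NIRS, columns (HbO, HbR)
DEFAULT_CHROMOPHORE = ChromophoreModel(np.array([[0.40, 1.10], [1.06, 0.69]]))


@dataclass
class ParcelTimeSeries:
    """Per-parcel ΔHbO series (samples × included parcels) with labels."""

    data: np.ndarray
    parcel_ids: np.ndarray
    network_labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("parcel series must be (samples, parcels)")
        if self.data.shape[1] != len(self.parcel_ids):
            raise ValueError("one id per parcel column required")
        if len(self.network_labels) != len(self.parcel_ids):
            raise ValueError("one network label per parcel required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


def sensitive_nodes(
    sensitivity: SensitivityMatrix,
    mask: ChannelMask | np.ndarray | None = None,
    threshold: float = 0.05,
) -> np.ndarray:
    """Boolean node mask: sensitive iff any kept channel sees the node.

    A node is sensitive when, for *any* kept channel at *either* wavelength,
    its row-normalised sensitivity strictly exceeds ``threshold`` of the
    channel-wise maximum.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if mask is None:
        keep = np.ones(sensitivity.n_channels, dtype=bool)
    elif isinstance(mask, ChannelMask):
        keep = mask.keep_channel
    else:
        keep = np.asarray(mask, dtype=bool)
    if keep.shape[0] != sensitivity.n_channels:
        raise ValueError("channel mask length mismatch")
    if not keep.any():
        warnings.warn("all channels pruned: no node is sensitive", stacklevel=2)
        return np.zeros(sensitivity.n_nodes, dtype=bool)
    jn = sensitivity.normalised()[:, keep, :]  # (W, kept, N)
    return (jn > threshold).any(axis=(0, 1))


def include_parcels(
    node_mask: np.ndarray, atlas: SyntheticAtlas, min_fraction: float = 0.5
) -> np.ndarray:
    """Parcel ids whose sensitive-node fraction strictly exceeds ``min_fraction``."""
    node_mask = np.asarray(node_mask, dtype=bool)
    if node_mask.shape[0] != atlas.n_nodes:
        raise ValueError("node mask length must equal atlas node count")
    included = []
    for pid in atlas.parcel_ids:
        nodes = atlas.nodes_of(pid)
        if node_mask[nodes].mean() > min_fraction:
            included.append(int(pid))
    return np.array(included, dtype=int)


def mbll_invert(
    dmua: np.ndarray, model: ChromophoreModel = DEFAULT_CHROMOPHORE
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer–Lambert system ΔC = ε⁻¹·Δμa per node/sample.

    ``dmua`` carries the two wavelengths on its last axis; returns
    (ΔHbO, ΔHbR) arrays of the remaining shape.
    """
    if not model.invertible:
        raise ValueError("extinction-coefficient matrix is singular")
    dmua = np.asarray(dmua, dtype=float)
    if dmua.shape[-1] != 2:
        raise ValueError("last axis must hold the two wavelengths")
    inv = np.linalg.inv(model.epsilon)
    conc = dmua @ inv.T
    return conc[..., 0], conc[..., 1]


def channel_to_nodes(
    od: ODTimeSeries, sensitivity: SensitivityMatrix, mask: ChannelMask | None = None
) -> np.ndarray:
    """Map channel ΔOD to node-space Δμa by normalised-sensitivity weighting.

    This is the synthetic-data stand-in for tomographic image
    reconstruction: each node receives the sensitivity-weighted average of
    the kept channels that see it, per wavelength.  Nodes seen by no kept
    channel are zero.  Returns (samples, nodes, wavelengths).
    """
    keep = mask.keep_channel if mask is not None else np.ones(od.n_channels, dtype=bool)
    keep = keep & od.computable.all(axis=1)
    jn = sensitivity.normalised()  # (W, C, N)
    n_w = jn.shape[0]
    out = np.zeros((od.n_samples, sensitivity.n_nodes, n_w))
    for w in range(n_w):
        jw = jn[w][keep]  # (kept, N)
        col = jw.sum(axis=0)  # (N,)
        weights = np.where(col > 0, jw / np.where(col > 0, col, 1.0), 0.0)
        out[:, :, w] = od.od[:, keep, w] @ weights
    return out


def parcel_average(
    node_series: np.ndarray,
    node_mask: np.ndarray,
    included: np.ndarray,
    atlas: SyntheticAtlas,
    fs: float,
) -> ParcelTimeSeries:
    """Average each included parcel's *sensitive* nodes into one series."""
    included = np.asarray(included, dtype=int)
    if included.size == 0:
        raise ValueError("no parcels included")
    node_series = np.asarray(node_series, dtype=float)
    node_mask = np.asarray(node_mask, dtype=bool)
    data = np.empty((node_series.shape[0], included.size))
    labels = np.empty(included.size, dtype=object)
    for k, pid in enumerate(included):
        nodes = atlas.nodes_of(pid)
        sens = nodes[node_mask[nodes]]
        if sens.size == 0:
            raise ValueError(f"included parcel {pid} has no sensitive nodes")
        data[:, k] = node_series[:, sens].mean(axis=1)
        labels[k] = atlas.network_of(pid)
    return ParcelTimeSeries(data=data, parcel_ids=included, network_labels=labels, fs=fs)


def global_signal_regress(pts: ParcelTimeSeries) -> tuple[ParcelTimeSeries, np.ndarray]:
    """Regress the across-parcel mean series out of every parcel (OLS).

    Returns the residual series and the global component.  Residuals are
    exactly orthogonal to the global component (zero sample covariance).
    """
    if pts.n_parcels < 2:
        raise ValueError("global signal regression needs at least two parcels")
    g = pts.data.mean(axis=1)
    gc = g - g.mean()
    denom = gc @ gc
    resid = np.empty_like(pts.data)
    for k in range(pts.n_parcels):
        y = pts.data[:, k]
        beta = (gc @ (y - y.mean())) / denom if denom > 0 else 0.0
        resid[:, k] = y - y.mean() - beta * gc
    out = ParcelTimeSeries(
        data=resid, parcel_ids=pts.parcel_ids, network_labels=pts.network_labels, fs=pts.fs
    )
    return out, g


def global_coupling(pts: ParcelTimeSeries, global_component: np.ndarray) -> float:
    """Mean Pearson correlation between each parcel and the global component.

    Computed on the *pre-regression* series; quantifies how much shared
    (typically systemic) signal each parcel carries.
    """
    g = np.asarray(global_component, dtype=float)
    if g.std() == 0:
        raise ValueError("global component is constant: coupling undefined")
    gz = (g - g.mean()) / g.std()
    rs = []
    for k in range(pts.n_parcels):
        y = pts.data[:, k]
        sd = y.std()
        if sd == 0:
            raise ValueError(f"parcel {pts.parcel_ids[k]} is constant")
        rs.append(float(np.mean(gz * (y - y.mean()) / sd)))
    return float(np.mean(rs))
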