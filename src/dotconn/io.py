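"""Readers and writers for the pipeline's file formats.

SNIRF support is a minimal, self-contained implementation of the SNIRF v1
HDF5 layout (dataTimeSeries + measurementList + probe) sufficient for
round-tripping the recordings this package produces and consumes.  CSV
variants exist for every artefact so a whole run can be inspected with a
text editor.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .atlas import SyntheticAtlas
from .graph import BrainGraph
from .parcel import ParcelTimeSeries, SensitivityMatrix
from .qc import ChannelRecording

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_channels_csv",
    "read_channels_csv",
    "write_atlas_csv",
    "read_atlas_csv",
    "write_sensitivity_h5",
    "read_sensitivity_h5",
    "write_parcel_csv",
    "read_parcel_csv",
    "write_adjacency_csv",
    "read_adjacency_csv",
    "write_edge_list",
    "write_json",
    "read_json",
    "write_yaml",
    "read_yaml",
    "config_hash",
]


def _str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def write_snirf(path: str | Path, rec: ChannelRecording) -> None:
    """Write a recording as a SNIRF v1 HDF5 file."""
    n, c, w = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries", data=rec.intensity.reshape(n, c * w, order="F")
        )
        data.create_dataset("time", data=np.arange(n) / rec.fs)
        k = 1
        for wav in range(w):
            for ch in range(c):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=int(rec.source_idx[ch]) + 1)
                ml.create_dataset("detectorIndex", data=int(rec.detector_idx[ch]) + 1)
                ml.create_dataset("wavelengthIndex", data=wav + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))
        probe.create_dataset("sourcePos3D", data=rec.source_pos)
        probe.create_dataset("detectorPos3D", data=rec.detector_pos)


def read_snirf(path: str | Path) -> ChannelRecording:
    """Read a SNIRF v1 file written by :func:`write_snirf` (or compatible)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if time.size < 2:
            raise ValueError("SNIRF time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList") :]),
        )
        src_i, det_i, wav_i = [], [], []
        for name in ml_names:
            g = data[name]
            src_i.append(int(np.asarray(g["sourceIndex"])) - 1)
            det_i.append(int(np.asarray(g["detectorIndex"])) - 1)
            wav_i.append(int(np.asarray(g["wavelengthIndex"])) - 1)
        probe = nirs["probe"]
        wavelengths = tuple(float(x) for x in np.asarray(probe["wavelengths"]))
        src_pos = np.asarray(probe["sourcePos3D"])
        det_pos = np.asarray(probe["detectorPos3D"])

    wav_i = np.asarray(wav_i)
    src_i = np.asarray(src_i)
    det_i = np.asarray(det_i)
    n_wav = len(wavelengths)
    cols0 = np.flatnonzero(wav_i == 0)
    n_ch = cols0.size
    intensity = np.empty((ts.shape[0], n_ch, n_wav))
    for w in range(n_wav):
        cols = np.flatnonzero(wav_i == w)
        intensity[:, :, w] = ts[:, cols]
    return ChannelRecording(
        intensity=intensity,
        fs=fs,
        source_idx=src_i[cols0],
        detector_idx=det_i[cols0],
        source_pos=src_pos,
        detector_pos=det_pos,
        wavelengths=wavelengths,
    )


def write_channels_csv(prefix: str | Path, rec: ChannelRecording) -> tuple[Path, Path]:
    """Write a recording as ``<prefix>_data.csv`` + ``<prefix>_geometry.csv``."""
    prefix = Path(prefix)
    n, c, w = rec.intensity.shape
    cols = {"time": np.arange(n) / rec.fs}
    for ch in range(c):
        for wav in range(w):
            cols[f"ch{ch}_wl{wav}"] = rec.intensity[:, ch, wav]
    data_path = prefix.with_name(prefix.name + "_data.csv")
    pd.DataFrame(cols).to_csv(data_path, index=False)

    geo = pd.DataFrame(
        {
            "channel": np.arange(c),
            "source": rec.source_idx,
            "detector": rec.detector_idx,
            "sx": rec.source_pos[rec.source_idx, 0],
            "sy": rec.source_pos[rec.source_idx, 1],
            "sz": rec.source_pos[rec.source_idx, 2],
            "dx": rec.detector_pos[rec.detector_idx, 0],
            "dy": rec.detector_pos[rec.detector_idx, 1],
            "dz": rec.detector_pos[rec.detector_idx, 2],
        }
    )
    geo_path = prefix.with_name(prefix.name + "_geometry.csv")
    geo.attrs["wavelengths"] = rec.wavelengths
    geo.to_csv(geo_path, index=False)
    return data_path, geo_path


def read_channels_csv(prefix: str | Path, wavelengths: tuple[float, ...] = (735.0, 850.0)) -> ChannelRecording:
    prefix = Path(prefix)
    data = pd.read_csv(prefix.with_name(prefix.name + "_data.csv"))
    geo = pd.read_csv(prefix.with_name(prefix.name + "_geometry.csv"))
    time = data["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(time)))
    c = len(geo)
    w = len(wavelengths)
    intensity = np.empty((len(data), c, w))
    for ch in range(c):
        for wav in range(w):
            intensity[:, ch, wav] = data[f"ch{ch}_wl{wav}"].to_numpy()
    src = geo["source"].to_numpy()
    det = geo["detector"].to_numpy()
    n_src = int(src.max()) + 1
    n_det = int(det.max()) + 1
    source_pos = np.zeros((n_src, 3))
    detector_pos = np.zeros((n_det, 3))
    source_pos[src] = geo[["sx", "sy", "sz"]].to_numpy()
    detector_pos[det] = geo[["dx", "dy", "dz"]].to_numpy()
    return ChannelRecording(
        intensity=intensity,
        fs=fs,
        source_idx=src,
        detector_idx=det,
        source_pos=source_pos,
        detector_pos=detector_pos,
        wavelengths=wavelengths,
    )


def write_atlas_csv(path: str | Path, atlas: SyntheticAtlas) -> None:
    rows = []
    for node, pid in enumerate(atlas.node_to_parcel):
        k = atlas.parcel_index(int(pid))
        rows.append(
            {
                "node": node,
                "parcel": int(pid),
                "network": str(atlas.network_labels[k]),
                "cx": atlas.centroids[k, 0],
                "cy": atlas.centroids[k, 1],
                "cz": atlas.centroids[k, 2],
                "nx": atlas.node_positions[node, 0],
                "ny": atlas.node_positions[node, 1],
                "nz": atlas.node_positions[node, 2],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_atlas_csv(path: str | Path) -> SyntheticAtlas:
    df = pd.read_csv(path)
    parcels = df.drop_duplicates("parcel").sort_values("parcel")
    return SyntheticAtlas(
        parcel_ids=parcels["parcel"].to_numpy(dtype=int),
        network_labels=parcels["network"].to_numpy(dtype=object),
        centroids=parcels[["cx", "cy", "cz"]].to_numpy(dtype=float),
        node_to_parcel=df.sort_values("node")["parcel"].to_numpy(dtype=int),
        node_positions=df.sort_values("node")[["nx", "ny", "nz"]].to_numpy(dtype=float),
    )


def write_sensitivity_h5(path: str | Path, sensitivity: SensitivityMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("jacobian", data=sensitivity.j)


def read_sensitivity_h5(path: str | Path) -> SensitivityMatrix:
    with h5py.File(path, "r") as f:
        return SensitivityMatrix(j=np.asarray(f["jacobian"]))


def write_parcel_csv(path: str | Path, pts: ParcelTimeSeries) -> None:
    cols = {"time": np.arange(pts.n_samples) / pts.fs}
    for k, pid in enumerate(pts.parcel_ids):
        cols[f"parcel{int(pid)}|{pts.network_labels[k]}"] = pts.data[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_parcel_csv(path: str | Path) -> ParcelTimeSeries:
    df = pd.read_csv(path)
    time = df["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(time)))
    ids, nets, series = [], [], []
    for col in df.columns:
        if not col.startswith("parcel"):
            continue
        head, net = col.split("|", 1)
        ids.append(int(head[len("parcel") :]))
        nets.append(net)
        series.append(df[col].to_numpy())
    return ParcelTimeSeries(
        data=np.column_stack(series),
        parcel_ids=np.asarray(ids, dtype=int),
        network_labels=np.asarray(nets, dtype=object),
        fs=fs,
    )


def write_adjacency_csv(path: str | Path, g: BrainGraph) -> None:
    ids = [int(p) for p in g.parcel_ids]
    df = pd.DataFrame(g.w, index=ids, columns=ids)
    df.index.name = "parcel"
    df.to_csv(path)


def read_adjacency_csv(path: str | Path, network_labels: np.ndarray | None = None) -> BrainGraph:
    df = pd.read_csv(path, index_col=0)
    w = df.to_numpy(dtype=float)
    ids = np.asarray([int(c) for c in df.columns])
    if network_labels is None:
        network_labels = np.asarray(["?"] * len(ids), dtype=object)
    return BrainGraph(w=w, sign=(w > 0).astype(int), parcel_ids=ids, network_labels=network_labels)


def write_edge_list(path: str | Path, g: BrainGraph, r: np.ndarray | None = None) -> None:
    """Edge list TSV: parcel_i, parcel_j, weight, sign, r."""
    rows = []
    ii, jj = np.nonzero(np.triu(g.w, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        rows.append(
            {
                "parcel_i": int(g.parcel_ids[i]),
                "parcel_j": int(g.parcel_ids[j]),
                "weight": g.w[i, j],
                "sign": int(g.sign[i, j]),
                "r": float(r[i, j]) if r is not None else np.nan,
            }
        )
    pd.DataFrame(rows, columns=["parcel_i", "parcel_j", "weight", "sign", "r"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
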