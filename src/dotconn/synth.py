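"""Synthetic HD-DOT cohort generator.

Generates everything the pipeline needs with no external data: a synthetic
atlas, block-correlated parcel time series with programmed group structure,
a probe layout with a channels×nodes sensitivity matrix, and raw channel
intensity recordings composed of a sensitivity-weighted neural mixture,
shared systemic physiology (Mayer waves ~0.1 Hz, respiration ~0.3 Hz,
cardiac ~1.1 Hz), measurement noise, and motion spikes.

The cohort mirrors the study design the pipeline targets: three groups of
22 healthy controls, 22 with mild cognitive impairment (MCI) and 21 with
Alzheimer's disease (AD), each recorded for 5 minutes at 12.5 Hz.  Group
differences are parameterised solely through the within/between-network
correlation pair (ρ_w, ρ_b): HC (0.30, 0.05), MCI (0.45, 0.15),
AD (0.30, 0.05) — the MCI group is hyperconnected, the direction the
pipeline's parameter-recovery tests look for.

Neural parcel series are drawn by bandpass-filtering white Gaussian noise
to 0.01–0.1 Hz and then imposing the block covariance through its Cholesky
factor, which preserves the target correlation exactly in expectation.
Short-separation channels (< 12 mm) carry scalp physiology and noise only;
their sensitivity rows are identically zero, so they contain no projection
of the neural signal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .atlas import SyntheticAtlas, make_atlas
from .parcel import ChromophoreModel, DEFAULT_CHROMOPHORE, SensitivityMatrix
from .qc import ChannelRecording

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "GroundTruth",
    "Probe",
    "Subject",
    "make_probe",
    "simulate_parcel_timeseries",
    "simulate_channel_recording",
    "generate_cohort",
    "DEFAULT_PROFILES",
]


@dataclass(frozen=True)
class GroupProfile:
    """Connectivity profile of one clinical group."""

    rho_within: float
    rho_between: float

    def __post_init__(self) -> None:
        for rho in (self.rho_within, self.rho_between):
            if not 0 <= rho < 1:
                raise ValueError("correlations must lie in [0, 1)")


DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "HC": GroupProfile(0.30, 0.05),
    "MCI": GroupProfile(0.45, 0.15),
    "AD": GroupProfile(0.30, 0.05),
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Physiology amplitudes are ΔOD units; the cardiac amplitude is the
    largest so the spectral heart-rate check succeeds on clean channels, as
    it does in real optical recordings.  Motion events are subject-level
    spikes shared across channels (a head movement moves the whole array).
    """

    n_hc: int = 22
    n_mci: int = 22
    n_ad: int = 21
    duration_s: float = 300.0
    fs: float = 12.5
    profiles: dict[str, GroupProfile] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    # physiology (ΔOD units)
    amp_mayer: float = 0.003
    amp_resp: float = 0.004
    amp_cardiac: float = 0.012
    f_mayer: float = 0.1
    f_resp: float = 0.3
    f_cardiac: float = 1.1
    # motion
    motion_rate_per_min: float = 0.5
    motion_amp: float = 0.1
    # noise and signal scaling
    noise_sd: float = 0.005
    neural_od_scale: float = 0.01
    hbr_ratio: float = -0.3
    chromophores: ChromophoreModel = field(default_factory=lambda: DEFAULT_CHROMOPHORE)
    baseline_intensity: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_hc, self.n_mci, self.n_ad) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        for name in ("HC", "MCI", "AD"):
            if name not in self.profiles:
                raise ValueError(f"missing profile for group {name}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"HC": self.n_hc, "MCI": self.n_mci, "AD": self.n_ad}


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    covariance: np.ndarray  # target parcel covariance
    partition: np.ndarray  # true module (network) label per parcel
    motion_mask: np.ndarray | None = None  # injected motion samples

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, dtype=float)
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("covariance must be positive semi-definite")
        if len(self.partition) != c.shape[0]:
            raise ValueError("partition must cover all parcels")


@dataclass
class Probe:
    """Synthetic optode layout: long channels over parcels plus scalp shorts."""

    source_pos: np.ndarray
    detector_pos: np.ndarray
    source_idx: np.ndarray
    detector_idx: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.source_idx)

    @property
    def separations(self) -> np.ndarray:
        return np.linalg.norm(
            self.source_pos[self.source_idx] - self.detector_pos[self.detector_idx], axis=1
        )

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.source_pos[self.source_idx] + self.detector_pos[self.detector_idx])


@dataclass
class Subject:
    """One synthetic participant: recording, ground truth, covariates."""

    subject_id: str
    group: str
    recording: ChannelRecording
    truth: GroundTruth
    covariates: dict


def block_covariance(atlas: SyntheticAtlas, rho_within: float, rho_between: float) -> np.ndarray:
    """Unit-variance covariance with ρ_w inside networks and ρ_b between."""
    labels = atlas.network_labels
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, rho_within, rho_between)
    np.fill_diagonal(cov, 1.0)
    return cov


def simulate_parcel_timeseries(
    atlas: SyntheticAtlas,
    profile: GroupProfile,
    duration_s: float = 300.0,
    fs: float = 12.5,
    seed: int = 0,
    band: tuple[float, float] = (0.01, 0.1),
) -> tuple[np.ndarray, GroundTruth]:
    """Draw band-limited parcel series with the profile's block covariance.

    White Gaussian noise is bandpass-filtered to ``band`` first (a single
    causal Butterworth pass, as a physiological band presents itself),
    column-wise standardised, then mixed through the Cholesky factor of the
    target covariance, so the sample correlation converges to the target as
    the record grows.  Returns (samples × parcels) series with unit variance
    in expectation, and the ground truth.
    """
    cov = block_covariance(atlas, profile.rho_within, profile.rho_between)
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10:
        raise ValueError("target covariance is not positive semi-definite")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n, atlas.n_parcels))
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfilt(sos, white, axis=0)
    filtered = filtered / filtered.std(axis=0, ddof=0)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(atlas.n_parcels))
    series = filtered @ chol.T
    truth = GroundTruth(covariance=cov, partition=atlas.network_labels.copy())
    return series, truth


def make_probe(
    atlas: SyntheticAtlas,
    n_short: int = 15,
    long_separation: float = 30.0,
    short_separation: float = 8.0,
    sensitivity_sigma: float = 8.0,
    seed: int = 0,
) -> tuple[Probe, SensitivityMatrix]:
    """One long channel per parcel plus ``n_short`` scalp-only short channels.

    Long-channel sensitivity to a node falls off as a Gaussian of the
    midpoint–node distance (width ``sensitivity_sigma`` mm); short channels
    have identically zero sensitivity (they sample scalp only).  The two
    wavelengths share the spatial profile up to a mild global factor.
    """
    rng = np.random.default_rng(seed)
    src, det, s_idx, d_idx = [], [], [], []
    for k in range(atlas.n_parcels):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        src.append(atlas.centroids[k] + 0.5 * long_separation * direction)
        det.append(atlas.centroids[k] - 0.5 * long_separation * direction)
        s_idx.append(len(src) - 1)
        d_idx.append(len(det) - 1)
    short_anchor = atlas.centroids[
        np.linspace(0, atlas.n_parcels - 1, max(1, n_short)).astype(int)
    ]
    for pos in short_anchor:
        src.append(pos + np.array([0.0, 0.0, 5.0]))
        det.append(pos + np.array([short_separation, 0.0, 5.0]))
        s_idx.append(len(src) - 1)
        d_idx.append(len(det) - 1)

    probe = Probe(
        source_pos=np.array(src),
        detector_pos=np.array(det),
        source_idx=np.array(s_idx),
        detector_idx=np.array(d_idx),
    )
    mids = probe.midpoints
    d2 = ((mids[:, None, :] - atlas.node_positions[None, :, :]) ** 2).sum(axis=2)
    j = np.exp(-d2 / (2.0 * sensitivity_sigma**2))
    j[atlas.n_parcels :, :] = 0.0  # short channels: scalp only
    jj = np.stack([j, 0.95 * j])
    return probe, SensitivityMatrix(j=jj)


def simulate_channel_recording(
    parcel_series: np.ndarray,
    atlas: SyntheticAtlas,
    probe: Probe,
    sensitivity: SensitivityMatrix,
    config: CohortConfig,
    seed: int = 0,
) -> tuple[ChannelRecording, np.ndarray]:
    """Compose channel intensities from neural, physiological and noise parts.

    Long-channel ΔOD at each wavelength is the row-normalised
    sensitivity-weighted mixture of node-level absorption changes (HbO plus
    a proportional HbR component through the extinction matrix), scaled by
    ``neural_od_scale``.  All channels share sinusoidal systemic physiology
    with per-channel gains; motion spikes are subject-level boxcar events.
    Intensities are ``baseline · exp(−ΔOD)``.  Returns the recording and the
    injected motion mask.
    """
    series = np.asarray(parcel_series, dtype=float)
    if sensitivity.n_nodes != atlas.n_nodes:
        raise ValueError("sensitivity node count must match the atlas")
    if sensitivity.n_channels != probe.n_channels:
        raise ValueError("sensitivity channel count must match the probe")
    n, n_parcels = series.shape
    if n_parcels != atlas.n_parcels:
        raise ValueError("parcel series width must match the atlas")

    rng = np.random.default_rng(seed)
    fs = config.fs
    t = np.arange(n) / fs

    parcel_col = {int(p): k for k, p in enumerate(atlas.parcel_ids)}
    node_cols = np.array([parcel_col[int(p)] for p in atlas.node_to_parcel])
    hbo = series[:, node_cols]  # (n, nodes)
    hbr = config.hbr_ratio * hbo
    eps = config.chromophores.epsilon
    jn = sensitivity.normalised()  # (W, C, N)
    n_wav = jn.shape[0]

    od = np.zeros((n, probe.n_channels, n_wav))
    for w in range(n_wav):
        mua = eps[w, 0] * hbo + eps[w, 1] * hbr  # (n, nodes)
        rows = jn[w].sum(axis=1)
        weights = np.where(rows[:, None] > 0, jn[w] / np.where(rows[:, None] > 0, rows[:, None], 1.0), 0.0)
        od[:, :, w] = config.neural_od_scale * (mua @ weights.T)

    # shared systemic physiology with per-channel gains; cardiac in all channels
    for amp, freq in (
        (config.amp_mayer, config.f_mayer),
        (config.amp_resp, config.f_resp),
        (config.amp_cardiac, config.f_cardiac),
    ):
        if amp == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * freq * t + phase)
        gains = rng.normal(1.0, 0.15, size=(probe.n_channels, n_wav))
        od += amp * wave[:, None, None] * gains[None, :, :]

    # motion: subject-level boxcar events hitting every channel
    motion_mask = np.zeros(n, dtype=bool)
    n_events = rng.poisson(config.motion_rate_per_min * config.duration_s / 60.0)
    event_len = max(1, int(round(0.24 * fs)))
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n - event_len)))
        sl = slice(start, start + event_len)
        motion_mask[sl] = True
        kick = config.motion_amp * rng.normal(size=(probe.n_channels, n_wav))
        od[sl] += kick[None, :, :]

    if config.noise_sd > 0:
        od += rng.normal(scale=config.noise_sd, size=od.shape)

    intensity = config.baseline_intensity * np.exp(-od)
    rec = ChannelRecording(
        intensity=intensity,
        fs=fs,
        source_idx=probe.source_idx,
        detector_idx=probe.detector_idx,
        source_pos=probe.source_pos,
        detector_pos=probe.detector_pos,
    )
    return rec, motion_mask


def generate_cohort(
    config: CohortConfig,
    atlas: SyntheticAtlas | None = None,
    probe: Probe | None = None,
    sensitivity: SensitivityMatrix | None = None,
) -> tuple[list[Subject], SyntheticAtlas, SensitivityMatrix]:
    """Generate the full cohort with deterministic per-subject seeds.

    Subject seeds are drawn once from the master seed in a fixed order, so
    the same master seed always yields a bit-identical cohort.  Covariates
    (age, MMSE, MTA) follow group-typical means; MTA is not rated for
    healthy controls, as in a study without control MRIs.
    """
    config.validate()
    if atlas is None:
        atlas = make_atlas(60, 10, nodes_per_parcel=5, seed=config.seed)
    if probe is None or sensitivity is None:
        probe, sensitivity = make_probe(atlas, seed=config.seed)

    master = np.random.default_rng(config.seed)
    cov_means = {  # (mmse mean, sd), (mta mean, sd)
        "HC": ((28.8, 1.15), None),
        "MCI": ((26.5, 2.23), (3.36, 1.8)),
        "AD": ((21.3, 4.35), (4.9, 1.5)),
    }
    subjects: list[Subject] = []
    for group in ("HC", "MCI", "AD"):
        profile = config.profiles[group]
        for k in range(config.group_sizes[group]):
            sseed = int(master.integers(0, 2**31 - 1))
            series, truth = simulate_parcel_timeseries(
                atlas, profile, config.duration_s, config.fs, seed=sseed
            )
            rec, motion = simulate_channel_recording(
                series, atlas, probe, sensitivity, config, seed=sseed + 1
            )
            truth = replace(truth, motion_mask=motion)
            crng = np.random.default_rng(sseed + 2)
            (mmse_mu, mmse_sd), mta = cov_means[group]
            covariates = {
                "group": group,
                "age": float(np.clip(crng.normal(74.0, 7.0), 55, 95)),
                "mmse": float(np.clip(crng.normal(mmse_mu, mmse_sd), 0, 30)),
                "mta": float(np.clip(crng.normal(*mta), 0, 8)) if mta else None,
            }
            subjects.append(
                Subject(
                    subject_id=f"{group}{k + 1:02d}",
                    group=group,
                    recording=rec,
                    truth=truth,
                    covariates=covariates,
                )
            )
    return subjects, atlas, sensitivity
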