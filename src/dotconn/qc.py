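"""Channel-space quality control and preprocessing for optical recordings.

Implements the channel-level half of the pipeline: pruning of bad channels,
conversion of raw intensities to optical-density changes, motion-artefact
quantification (no correction is applied, only quantification), zero-phase
Butterworth bandpass filtering, and short-separation channel regression to
remove scalp haemodynamics from long channels.

Conventions
-----------
* ΔOD uses the natural-log Homer convention, ΔOD(t) = −ln(|I(t)| / mean|I|).
* Channel pruning thresholds are strict upper bounds: a channel is rejected
  only when a statistic is *above* its threshold.
* Cardiac detection = the spectral argmax (after linear detrend, DC bin
  excluded) lies inside the heart-rate band, 0.5–2 Hz by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "ChannelRecording",
    "ChannelMask",
    "ODTimeSeries",
    "MotionReport",
    "prune_channels",
    "detect_heart_rate",
    "intensity_to_od",
    "detect_motion",
    "bandpass",
    "bandpass_array",
    "short_channel_regress",
]

HEART_RATE_BAND = (0.5, 2.0)


@dataclass
class ChannelRecording:
    """Raw two-wavelength channel intensities with probe geometry.

    ``intensity`` has shape (n_samples, n_channels, n_wavelengths) in
    arbitrary detector units.  Geometry is carried per channel through
    source/detector indices into the position tables (mm).
    """

    intensity: np.ndarray
    fs: float
    source_idx: np.ndarray
    detector_idx: np.ndarray
    source_pos: np.ndarray
    detector_pos: np.ndarray
    wavelengths: tuple[float, ...] = (735.0, 850.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (samples, channels, wavelengths)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.intensity.shape[2] != len(self.wavelengths):
            raise ValueError("wavelength axis does not match wavelength list")
        if len(self.source_idx) != self.n_channels or len(self.detector_idx) != self.n_channels:
            raise ValueError("per-channel geometry indices required")
        if np.any(self.separations < 0):
            raise ValueError("separations must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_wavelengths(self) -> int:
        return self.intensity.shape[2]

    @property
    def separations(self) -> np.ndarray:
        """Source–detector separation per channel, mm."""
        return np.linalg.norm(
            self.source_pos[self.source_idx] - self.detector_pos[self.detector_idx], axis=1
        )

    @property
    def midpoints(self) -> np.ndarray:
        """Channel midpoints (mm), used for nearest-short-channel lookup."""
        return 0.5 * (self.source_pos[self.source_idx] + self.detector_pos[self.detector_idx])


@dataclass
class ChannelMask:
    """Keep/reject decision per channel per wavelength, with a reason.

    Rejection reasons are channel-level and one of ``"cov"``,
    ``"intensity"``, ``"separation"``, ``"no-cardiac"`` (empty string for
    kept channels).  A channel flagged for any reason is not kept.
    """

    keep: np.ndarray  # (n_channels, n_wavelengths) bool
    reasons: np.ndarray  # (n_channels,) object

    def __post_init__(self) -> None:
        flagged = np.array([r != "" for r in self.reasons])
        if np.any(self.keep[flagged]):
            raise ValueError("a channel with a rejection reason cannot be kept")

    @property
    def keep_channel(self) -> np.ndarray:
        """Channel-level keep flag (kept at every wavelength)."""
        return self.keep.all(axis=1)

    @property
    def n_kept(self) -> int:
        return int(self.keep_channel.sum())


@dataclass
class ODTimeSeries:
    """ΔOD (dimensionless) with geometry carried over from the recording."""

    od: np.ndarray  # (n_samples, n_channels, n_wavelengths)
    fs: float
    separations: np.ndarray
    midpoints: np.ndarray
    wavelengths: tuple[float, ...] = (735.0, 850.0)
    computable: np.ndarray | None = None  # (n_channels, n_wavelengths) bool

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValueError("od must be (samples, channels, wavelengths)")
        if self.computable is None:
            self.computable = np.ones(self.od.shape[1:], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]


@dataclass
class MotionReport:
    """Subject-level motion mask and burden (% of samples flagged)."""

    mask: np.ndarray  # (n_samples,) bool
    burden: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.burden <= 100.0:
            raise ValueError("burden must lie in [0, 100]")


def detect_heart_rate(
    series: np.ndarray, fs: float, band: tuple[float, float] = HEART_RATE_BAND
) -> bool:
    """True iff the dominant spectral peak of ``series`` lies in the heart-rate band.

    The series is linearly detrended and the DC bin excluded before taking the
    argmax of the magnitude spectrum; without detrending, slow drift dominates
    the spectrum and cardiac pulsation is never the peak.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise ValueError("need a 1-D series of at least 64 samples")
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low to resolve {band[1]} Hz")
    xd = signal.detrend(x, type="linear")
    spec = np.abs(np.fft.rfft(xd))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    peak = freqs[1:][np.argmax(spec[1:])]
    return bool(band[0] <= peak <= band[1])


def prune_channels(
    rec: ChannelRecording,
    cov_max: float = 8.3,
    intensity_max: float = 1e11,
    separation_max: float = 100.0,
    require_cardiac: bool = True,
) -> ChannelMask:
    """Flag channels failing any quality criterion.

    A channel is kept iff its mean coefficient of variation (across
    wavelengths, in %) is ≤ ``cov_max``, its mean intensity at every
    wavelength is ≤ ``intensity_max``, its source–detector separation is
    ≤ ``separation_max`` mm, and a cardiac peak is detectable at every
    wavelength.  All rejections use strict "above threshold" semantics, so
    values exactly at a threshold are kept.
    """
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ValueError("empty recording")

    mean = rec.intensity.mean(axis=0)  # (C, W)
    sd = rec.intensity.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = 100.0 * sd / np.abs(mean)
    cov = np.where(np.isfinite(cov), cov, np.inf)
    mean_cov = cov.mean(axis=1)  # (C,)

    seps = rec.separations
    reasons = np.array([""] * rec.n_channels, dtype=object)
    keep_ch = np.ones(rec.n_channels, dtype=bool)

    for c in range(rec.n_channels):
        if mean_cov[c] > cov_max:
            reasons[c] = "cov"
        elif np.any(mean[c] > intensity_max):
            reasons[c] = "intensity"
        elif seps[c] > separation_max:
            reasons[c] = "separation"
        elif require_cardiac and not all(
            detect_heart_rate(rec.intensity[:, c, w], rec.fs)
            for w in range(rec.n_wavelengths)
        ):
            reasons[c] = "no-cardiac"
        keep_ch[c] = reasons[c] == ""

    keep = np.repeat(keep_ch[:, None], rec.n_wavelengths, axis=1)
    return ChannelMask(keep=keep, reasons=reasons)


def intensity_to_od(rec: ChannelRecording) -> ODTimeSeries:
    """Convert raw intensities to ΔOD = −ln(|I| / mean|I|) per channel/wavelength.

    Channels whose intensity is identically zero (or contains zeros, making
    the log diverge) are flagged not-computable rather than raising; their OD
    is NaN.
    """
    absI = np.abs(rec.intensity)
    mean = absI.mean(axis=0)  # (C, W)
    computable = mean > 0
    od = np.full_like(rec.intensity, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = absI / np.where(mean > 0, mean, np.nan)
        od = -np.log(ratio)
    bad = ~np.isfinite(od).all(axis=0)
    computable &= ~bad
    od[:, ~computable] = np.nan
    return ODTimeSeries(
        od=od,
        fs=rec.fs,
        separations=rec.separations,
        midpoints=rec.midpoints,
        wavelengths=rec.wavelengths,
        computable=computable,
    )


def detect_motion(
    od: ODTimeSeries,
    amp_thresh: float = 0.5,
    std_thresh: float = 10.0,
    t_motion: float = 0.5,
    t_mask: float = 1.0,
    mask: ChannelMask | None = None,
) -> MotionReport:
    """Quantify motion burden from ΔOD excursions (no correction applied).

    For every kept channel/wavelength, each sliding window of length
    ``t_motion`` whose range (max − min) exceeds ``amp_thresh`` or
    ``std_thresh`` × the channel SD flags the window's start sample; flags
    are unioned over channels and dilated by ±``t_mask``.  Burden is the
    flagged percentage of samples.
    """
    if t_motion <= 0 or t_mask <= 0:
        raise ValueError("t_motion and t_mask must be positive")
    n = od.n_samples
    w = max(2, int(round(t_motion * od.fs)))
    if w > n:
        raise ValueError("motion window longer than the record")

    keep = mask.keep if mask is not None else np.ones(od.od.shape[1:], dtype=bool)
    keep = keep & od.computable
    flags = np.zeros(n, dtype=bool)
    cols = np.argwhere(keep)
    if cols.size:
        X = od.od[:, cols[:, 0], cols[:, 1]]  # (n, n_kept_series)
        win = np.lib.stride_tricks.sliding_window_view(X, w, axis=0)  # (n-w+1, k, w)
        rng_ = win.max(axis=-1) - win.min(axis=-1)
        sd = X.std(axis=0, ddof=0)
        bad = (rng_ > amp_thresh) | (rng_ > std_thresh * sd[None, :])
        flags[: n - w + 1] = bad.any(axis=1)

    radius = int(round(t_mask * od.fs))
    if radius > 0 and flags.any():
        flags = ndimage.binary_dilation(flags, structure=np.ones(2 * radius + 1, dtype=bool))
    burden = 100.0 * flags.mean()
    return MotionReport(mask=flags, burden=float(burden))


def bandpass_array(
    x: np.ndarray, fs: float, low: float = 0.01, high: float = 0.1, order: int = 3, axis: int = 0
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of an array along ``axis``."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={fs} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=axis)


def bandpass(
    od: ODTimeSeries, low: float = 0.01, high: float = 0.1, order: int = 3
) -> ODTimeSeries:
    """Zero-phase (forward–backward) Butterworth bandpass of every channel.

    Applied forward and backward the effective magnitude response is the
    squared single-pass response; output length equals input length.
    """
    data = od.od
    filt = np.full_like(data, np.nan)
    ok = od.computable
    if ok.any():
        cols = np.argwhere(ok)
        filt[:, cols[:, 0], cols[:, 1]] = bandpass_array(
            data[:, cols[:, 0], cols[:, 1]], od.fs, low, high, order, axis=0
        )
    return replace(od, od=filt)


def short_channel_regress(
    od: ODTimeSeries, mask: ChannelMask, short_max: float = 12.0
) -> ODTimeSeries:
    """Regress the nearest short-separation channel out of every long channel.

    Short channels (< ``short_max`` mm) are assumed to sample scalp
    haemodynamics only.  For each kept long channel the ordinary
    least-squares fit (with intercept) of its nearest short channel at the
    same wavelength is subtracted; short channels pass through unchanged.
    """
    keep_ch = mask.keep_channel
    short = keep_ch & (od.separations < short_max)
    long_ = keep_ch & ~short
    if not short.any():
        raise ValueError(
            "no kept short-separation channels: skip short-channel regression explicitly"
        )

    short_ix = np.flatnonzero(short)
    out = od.od.copy()
    d = np.linalg.norm(
        od.midpoints[:, None, :] - od.midpoints[short_ix][None, :, :], axis=2
    )  # (C, n_short)
    nearest = short_ix[np.argmin(d, axis=1)]

    for c in np.flatnonzero(long_):
        s = nearest[c]
        for w in range(od.od.shape[2]):
            y = od.od[:, c, w]
            x = od.od[:, s, w]
            if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
                continue
            xc = x - x.mean()
            denom = xc @ xc
            beta = (xc @ (y - y.mean())) / denom if denom > 0 else 0.0
            out[:, c, w] = y - y.mean() - beta * xc
    return replace(od, od=out)
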