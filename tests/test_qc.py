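"""Channel QC: pruning, cardiac detection, OD conversion, motion, filtering."""

import numpy as np
import pytest

from dotconn.qc import (
    ChannelRecording,
    ChannelMask,
    bandpass,
    detect_heart_rate,
    detect_motion,
    intensity_to_od,
    prune_channels,
    short_channel_regress,
)

FS = 12.5


def make_recording(intensity, separations):
    """Recording with channels laid out along x at the requested separations."""
    intensity = np.asarray(intensity, dtype=float)
    n_ch = intensity.shape[1]
    src = np.array([[10.0 * c, 0.0, 0.0] for c in range(n_ch)])
    det = np.array([[10.0 * c + separations[c], 0.0, 0.0] for c in range(n_ch)])
    return ChannelRecording(
        intensity=intensity,
        fs=FS,
        source_idx=np.arange(n_ch),
        detector_idx=np.arange(n_ch),
        source_pos=src,
        detector_pos=det,
    )


def cardiac(n, amp=1.0, f=1.2):
    t = np.arange(n) / FS
    return amp * np.sin(2 * np.pi * f * t)


class TestDetectHeartRate:
    def test_cardiac_sine_detected(self):
        assert detect_heart_rate(cardiac(3750, f=1.2), FS)

    def test_slow_sine_not_detected(self):
        assert not detect_heart_rate(cardiac(3750, f=0.2), FS)

    def test_drift_removed_by_detrend(self):
        n = 3750
        x = cardiac(n, amp=1.0, f=1.0) + 0.2 * np.linspace(0, 1, n)
        assert detect_heart_rate(x, FS)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_heart_rate(np.zeros(10), FS)


class TestPruneChannels:
    def test_clean_channel_kept(self):
        n = 3750
        base = 1e6 + 1e3 * cardiac(n)  # CoV ~0.07%, cardiac present
        rec = make_recording(np.dstack([base, base])[0][:, None, :], [30.0])
        mask = prune_channels(rec)
        assert mask.keep_channel[0]
        assert mask.reasons[0] == ""

    def test_high_cov_rejected(self):
        n = 3750
        rng = np.random.default_rng(0)
        noisy = 1e6 * (1 + 0.10 * rng.standard_normal(n))  # CoV ~10% > 8.3%
        rec = make_recording(np.dstack([noisy, noisy])[0][:, None, :], [30.0])
        mask = prune_channels(rec)
        assert not mask.keep_channel[0]
        assert mask.reasons[0] == "cov"

    def test_cov_boundary_is_strict(self):
        # rejection requires CoV strictly above the threshold: a channel whose
        # CoV equals the threshold exactly is kept
        n = 3750
        x = 1e6 * (1 + 0.05 * np.sign(cardiac(n, f=1.2)))
        rec = make_recording(np.dstack([x, x])[0][:, None, :], [30.0])
        cov_actual = 100.0 * x.std() / x.mean()
        kept = prune_channels(rec, cov_max=cov_actual)
        rejected = prune_channels(rec, cov_max=cov_actual - 1e-9)
        assert kept.keep_channel[0]
        assert not rejected.keep_channel[0] and rejected.reasons[0] == "cov"

    def test_separation_and_intensity_rules(self):
        n = 3750
        base = 1e6 + 1e3 * cardiac(n)
        bright = 1e12 + 1e9 * cardiac(n)
        intensity = np.stack([base, bright, base], axis=1)
        rec = make_recording(np.dstack([intensity, intensity]), [30.0, 30.0, 150.0])
        mask = prune_channels(rec)
        assert mask.reasons.tolist() == ["", "intensity", "separation"]

    def test_no_cardiac_rejected(self):
        n = 3750
        rng = np.random.default_rng(1)
        flat = 1e6 * (1 + 1e-4 * rng.standard_normal(n))
        rec = make_recording(np.dstack([flat, flat])[0][:, None, :], [30.0])
        mask = prune_channels(rec)
        assert mask.reasons[0] == "no-cardiac"

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            prune_channels(
                make_recording(np.zeros((0, 1, 2)), [30.0])
            )

    def test_idempotent_and_deterministic(self):
        n = 1000
        rng = np.random.default_rng(2)
        x = 1e6 * (1 + 0.01 * rng.standard_normal((n, 3, 2))) + cardiac(n)[:, None, None] * 1e3
        rec = make_recording(x, [30.0, 8.0, 40.0])
        m1 = prune_channels(rec)
        m2 = prune_channels(rec)
        np.testing.assert_array_equal(m1.keep, m2.keep)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self):
        rec = make_recording(np.full((100, 1, 2), 5e5), [30.0])
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.od, 0.0, atol=1e-12)

    def test_closed_form_point(self):
        x = np.full(100, 2.0)
        x[50] = 2.0 * np.exp(-0.5)
        # mean(|I|) is slightly below 2; use the exact closed form
        rec = make_recording(np.dstack([x, x])[0][:, None, :], [30.0])
        od = intensity_to_od(rec)
        expected = -np.log(x / np.abs(x).mean())
        np.testing.assert_allclose(od.od[:, 0, 0], expected)
        assert od.od[50, 0, 0] == pytest.approx(0.5 + np.log(x.mean() / 2.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = 1e5 * (1 + 0.01 * rng.standard_normal((200, 1, 2)))
        od1 = intensity_to_od(make_recording(x, [30.0]))
        od2 = intensity_to_od(make_recording(10 * x, [30.0]))
        np.testing.assert_allclose(od1.od, od2.od, atol=1e-12)

    def test_all_zero_channel_flagged(self):
        x = np.zeros((100, 2, 2))
        x[:, 1, :] = 1e5
        od = intensity_to_od(make_recording(x, [30.0, 30.0]))
        assert not od.computable[0].any()
        assert od.computable[1].all()
        assert np.isnan(od.od[:, 0]).all()


class TestDetectMotion:
    def _od(self, data):
        rec = make_recording(np.exp(-np.asarray(data)) * 1e6, [30.0] * data.shape[1])
        return intensity_to_od(rec)

    def test_flat_record_zero_burden(self):
        rng = np.random.default_rng(4)
        od = self._od(0.001 * rng.standard_normal((3750, 2, 2)))
        assert detect_motion(od).burden == 0.0

    def test_single_step_burden_matches_mask_geometry(self):
        data = np.zeros((3750, 1, 2))
        data[1800:, 0, :] = 1.0  # step of height 1.0 > amp threshold 0.5
        report = detect_motion(self._od(data))
        # continuous-time arithmetic: (t_motion + 2 t_mask)/300 s = 0.833%;
        # discrete windows at 12.5 Hz give 0.80%
        assert report.burden == pytest.approx(0.833, abs=0.06)

    def test_subthreshold_oscillation_ignored(self):
        t = np.arange(3750) / FS
        data = 0.05 * np.sin(2 * np.pi * 0.5 * t)[:, None, None] * np.ones((1, 1, 2))
        assert detect_motion(self._od(data)).burden == 0.0

    def test_burden_monotone_in_spike_count(self):
        burdens = []
        for n_spikes in (1, 3, 6):
            data = np.zeros((3750, 1, 2))
            for k in range(n_spikes):
                data[400 + 500 * k : 403 + 500 * k, 0, :] = 2.0
            burdens.append(detect_motion(self._od(data)).burden)
        assert burdens == sorted(burdens)
        assert burdens[0] < burdens[-1]

    def test_window_longer_than_record_rejected(self):
        od = self._od(np.zeros((4, 1, 2)))
        with pytest.raises(ValueError):
            detect_motion(od, t_motion=10.0)


class TestBandpass:
    def _probe(self, freq, n=12500):
        t = np.arange(n) / FS
        data = np.sin(2 * np.pi * freq * t)[:, None, None] * np.ones((1, 1, 2))
        rec = make_recording(np.exp(-data) * 1e6, [30.0])
        return intensity_to_od(rec)

    def test_passband_gain(self):
        od = bandpass(self._probe(0.05))
        mid = od.od[2000:-2000, 0, 0]
        assert mid.max() >= 0.9

    def test_stopband_attenuation(self):
        od = bandpass(self._probe(1.0))
        mid = od.od[2000:-2000, 0, 0]
        assert np.abs(mid).max() <= 0.01

    def test_zero_input_zero_output(self):
        od = self._probe(0.05)
        od.od[:] = 0.0
        out = bandpass(od)
        np.testing.assert_allclose(out.od, 0.0, atol=1e-12)

    def test_invalid_band_rejected(self):
        od = self._probe(0.05, n=500)
        with pytest.raises(ValueError):
            bandpass(od, low=0.1, high=0.01)
        with pytest.raises(ValueError):
            bandpass(od, low=0.01, high=7.0)  # above Nyquist

    def test_length_preserved(self):
        od = self._probe(0.03, n=700)
        assert bandpass(od).od.shape == od.od.shape


class TestShortChannelRegress:
    def _setup(self, long_series, short_series):
        n = len(long_series)
        data = np.stack([long_series, short_series], axis=1)
        data = np.dstack([data, data])
        rec = make_recording(np.exp(-data) * 1e6, [30.0, 8.0])
        od = intensity_to_od(rec)
        od.od[:] = data  # use the raw series directly, no OD round-off
        mask = ChannelMask(
            keep=np.ones((2, 2), dtype=bool), reasons=np.array(["", ""], dtype=object)
        )
        return od, mask

    def test_identical_series_cancel(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(1000)
        od, mask = self._setup(s, s)
        out = short_channel_regress(od, mask)
        np.testing.assert_allclose(out.od[:, 0, :], 0.0, atol=1e-10)

    def test_orthogonal_series_unchanged(self):
        n = 1000
        t = np.arange(n)
        long_ = np.sin(2 * np.pi * 5 * t / n)
        short = np.cos(2 * np.pi * 5 * t / n)  # zero sample covariance
        od, mask = self._setup(long_, short)
        out = short_channel_regress(od, mask)
        np.testing.assert_allclose(out.od[:, 0, 0], long_ - long_.mean(), atol=1e-9)

    def test_snr1_neural_recovery(self):
        rng = np.random.default_rng(7)
        n = 3750
        scalp = rng.standard_normal(n)
        neural = rng.standard_normal(n)
        neural *= 0.8 * scalp.std() / neural.std()  # SNR 1 vs the 0.8·scalp part
        long_ = 0.8 * scalp + neural
        od, mask = self._setup(long_, scalp)
        out = short_channel_regress(od, mask)
        r = np.corrcoef(out.od[:, 0, 0], neural)[0, 1]
        assert r > 0.95

    def test_never_increases_rss(self):
        rng = np.random.default_rng(8)
        long_ = rng.standard_normal(500)
        short = 0.5 * long_ + rng.standard_normal(500)
        od, mask = self._setup(long_, short)
        out = short_channel_regress(od, mask)
        rss_before = np.sum((long_ - long_.mean()) ** 2)
        rss_after = np.sum(out.od[:, 0, 0] ** 2)
        assert rss_after <= rss_before + 1e-9

    def test_no_short_channels_is_explicit_error(self):
        rng = np.random.default_rng(9)
        data = np.dstack([rng.standard_normal((100, 2))] * 2)
        rec = make_recording(np.exp(-data) * 1e6, [30.0, 40.0])
        od = intensity_to_od(rec)
        mask = ChannelMask(
            keep=np.ones((2, 2), dtype=bool), reasons=np.array(["", ""], dtype=object)
        )
        with pytest.raises(ValueError, match="skip"):
            short_channel_regress(od, mask)
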