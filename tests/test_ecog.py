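"""ECoG filtering, band power and seizure-like-event detection."""

import numpy as np
import pytest

from sphenostim.ecog_spectral import (
    DEFAULT_BANDS,
    EventDetectionConfig,
    EventList,
    band_powers,
    bandpass_zero_phase,
    detect_seizure_like_events,
    spectral_power,
)
from sphenostim.io_core import TimeSeries
from sphenostim.synthetic_data import EcogEvent, EcogSpec, make_ecog

FS = 1000.0


def _tone(freq_hz, duration_s=60.0, amp=1.0):
    t = np.arange(int(duration_s * FS)) / FS
    return TimeSeries(amp * np.sin(2 * np.pi * freq_hz * t), fs_hz=FS, unit="ecog_uv")


class TestBandpassZeroPhase:
    def test_passband_tone_gain_and_zero_lag(self):
        x = _tone(10.0)
        y = bandpass_zero_phase(x)
        core = slice(int(5 * FS), int(55 * FS))  # away from edges
        gain = np.std(y.values[core]) / np.std(x.values[core])
        assert 0.95 <= gain <= 1.0
        lag = np.argmax(np.correlate(y.values[core], x.values[core], mode="full"))
        assert lag == len(x.values[core]) - 1  # zero-lag peak

    def test_stopband_tone_attenuated(self):
        x = _tone(0.5, duration_s=120.0)
        y = bandpass_zero_phase(x)
        core = slice(int(20 * FS), int(100 * FS))
        assert np.std(y.values[core]) / np.std(x.values[core]) < 0.1

    def test_zero_signal_stays_zero(self):
        x = TimeSeries(np.zeros(5000), fs_hz=FS, unit="ecog_uv")
        np.testing.assert_allclose(bandpass_zero_phase(x).values, 0.0)

    def test_hi_above_nyquist_rejected(self):
        x = _tone(10.0, duration_s=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_zero_phase(x, 2.0, 600.0)


class TestBandPowers:
    def test_band_edges_are_the_five_canonical_bands(self):
        assert DEFAULT_BANDS == ((2, 4), (5, 10), (11, 45), (46, 70), (71, 90))

    def test_pure_8hz_tone_concentrates_in_5_10(self):
        bp = band_powers(_tone(8.0))
        assert bp.band_fraction(5.0, 10.0) >= 0.95

    def test_per_session_powers_sum_to_one(self):
        bg, _ = make_ecog(EcogSpec(duration_s=60.0), seed=2)
        bp = band_powers(bg, normalization="per_session")
        assert bp.power.sum() == pytest.approx(1.0)

    def test_to_day1_requires_reference(self):
        bg, _ = make_ecog(EcogSpec(duration_s=60.0), seed=2)
        with pytest.raises(ValueError, match="day-1"):
            band_powers(bg, normalization="to_day1")

    def test_to_day1_self_reference_is_unity(self):
        bg, _ = make_ecog(EcogSpec(duration_s=60.0), seed=2)
        day1 = band_powers(bg, normalization="none")
        bp = band_powers(bg, normalization="to_day1", day1=day1)
        np.testing.assert_allclose(bp.power, 1.0)

    def test_white_noise_powers_proportional_to_bandwidth(self):
        """Flat-spectrum oracle: band share tracks bandwidth share (10-min signal)."""
        bg, _ = make_ecog(EcogSpec(duration_s=600.0, alpha=0.0), seed=17)
        bp = band_powers(bg, normalization="none")
        widths = np.array([hi - lo for lo, hi in DEFAULT_BANDS])
        ratio = (bp.raw_power / bp.raw_power.sum()) / (widths / widths.sum())
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_parseval_consistency(self):
        """Integrated 2-90 Hz spectral power tracks band-passed variance within 5%."""
        pink, _ = make_ecog(EcogSpec(duration_s=300.0), seed=8)
        filtered = bandpass_zero_phase(pink)
        f, pxx = spectral_power(filtered)
        df = f[1] - f[0]
        total = pxx[(f >= 2.0) & (f <= 90.0)].sum() * df
        assert total / np.var(filtered.values) == pytest.approx(1.0, abs=0.05)


class TestEventList:
    def test_burden_arithmetic(self):
        ev = EventList(events=[(100.0, 4.0)], recording_length_s=3600.0,
                       threshold_sd=3.0, baseline_sd_uv=50.0)
        assert ev.fast_activity_sec_per_h == pytest.approx(4.0)

    def test_burden_conservation(self):
        events = [(10.0, 2.0), (50.0, 3.5), (90.0, 1.0)]
        ev = EventList(events=events, recording_length_s=1800.0,
                       threshold_sd=3.0, baseline_sd_uv=50.0)
        hours = ev.recording_length_s / 3600.0
        assert ev.fast_activity_sec_per_h * hours == pytest.approx(6.5)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            EventList(events=[(10.0, 5.0), (12.0, 2.0)], recording_length_s=100.0,
                      threshold_sd=3.0, baseline_sd_uv=50.0)


@pytest.fixture(scope="module")
def baseline():
    ts, _ = make_ecog(EcogSpec(duration_s=120.0), seed=99)
    return ts


class TestDetectSeizureLikeEvents:
    def test_background_only_no_events(self, baseline):
        bg, _ = make_ecog(EcogSpec(duration_s=600.0), seed=123)
        det = detect_seizure_like_events(bg, baseline)
        assert det.n_events == 0

    def test_injected_events_recovered(self, baseline):
        events = [EcogEvent(onset_s=60.0 + 120.0 * k, duration_s=4.0,
                            carrier_band_hz=(80.0, 80.0)) for k in range(4)]
        sess, truth = make_ecog(EcogSpec(duration_s=600.0, events=events), seed=7)
        det = detect_seizure_like_events(sess, baseline)
        assert det.n_events == 4
        for onset, _ in det.events:
            assert min(abs(onset - t) for t in truth.onset_s) <= 0.5

    def test_amplitude_scale_equivariance(self, baseline):
        """Scaling signal and baseline by the same constant leaves events unchanged."""
        events = [EcogEvent(onset_s=30.0, duration_s=3.0)]
        sess, _ = make_ecog(EcogSpec(duration_s=120.0, events=events), seed=5)
        det1 = detect_seizure_like_events(sess, baseline)
        scaled_sess = TimeSeries(sess.values * 4.2, fs_hz=FS, unit="ecog_uv")
        scaled_base = TimeSeries(baseline.values * 4.2, fs_hz=FS, unit="ecog_uv")
        det2 = detect_seizure_like_events(scaled_sess, scaled_base)
        assert det1.events == det2.events

    def test_fs_mismatch_rejected(self, baseline):
        other = TimeSeries(np.random.default_rng(0).normal(0, 50, 70000),
                           fs_hz=500.0, unit="ecog_uv")
        with pytest.raises(ValueError, match="mismatch"):
            detect_seizure_like_events(other, baseline)

    def test_short_baseline_rejected(self):
        short, _ = make_ecog(EcogSpec(duration_s=30.0), seed=1)
        sess, _ = make_ecog(EcogSpec(duration_s=120.0), seed=2)
        with pytest.raises(ValueError, match="60"):
            detect_seizure_like_events(sess, short)
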