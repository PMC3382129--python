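"""ECoG spectral analysis and seizure-like-event detection.

The signal is band-passed 2–90 Hz with zero-phase (forward–backward)
Butterworth filtering, band power is summed over the five canonical
bands 2–4, 5–10, 11–45, 46–70 and 71–90 Hz from an averaged Hann-taper
periodogram, and seizure-like events are episodes whose amplitude
envelope exceeds 3 standard deviations of the day-1 baseline while the
71–90 Hz band is simultaneously elevated. The total event time per
recording hour is the fast-activity burden (s/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_core import TimeSeries

__all__ = [
    "DEFAULT_BANDS",
    "BandPowerSummary",
    "EventList",
    "EventDetectionConfig",
    "bandpass_zero_phase",
    "spectral_power",
    "band_powers",
    "detect_seizure_like_events",
]

#: the five analysis bands (lo_hz, hi_hz)
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (2.0, 4.0),
    (5.0, 10.0),
    (11.0, 45.0),
    (46.0, 70.0),
    (71.0, 90.0),
)


def bandpass_zero_phase(
    x: TimeSeries, lo_hz: float = 2.0, hi_hz: float = 90.0, order: int = 4
) -> TimeSeries:
    """Zero-phase band-pass: Butterworth applied forward and backward.

    Each pass is an ``order``-th Butterworth band-pass; the
    forward-backward application doubles the effective order and
    cancels the phase. Edge transients are handled by signal
    reflection (odd extension).
    """
    if hi_hz >= x.fs_hz / 2:
        raise ValueError(f"hi_hz={hi_hz} must be below Nyquist ({x.fs_hz / 2} Hz)")
    if not 0 < lo_hz < hi_hz:
        raise ValueError("need 0 < lo_hz < hi_hz")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=x.fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, x.values, padtype="odd")
    meta = dict(x.meta)
    meta.update(bandpass_hz=(lo_hz, hi_hz), filter_order_per_pass=order)
    return TimeSeries(y, fs_hz=x.fs_hz, unit=x.unit, t0_s=x.t0_s, meta=meta)


def spectral_power(x: TimeSeries, window_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum by averaged periodogram.

    Non-overlapping windows of ``window_s`` seconds with a Hann taper;
    returns frequencies and power spectral density (unit²/Hz), so that
    ``sum(Pxx) * df`` approximates the signal variance.
    """
    nperseg = int(round(window_s * x.fs_hz))
    if x.n < nperseg:
        nperseg = x.n
    f, pxx = sps.welch(
        x.values,
        fs=x.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
        scaling="density",
    )
    return f, pxx


@dataclass
class BandPowerSummary:
    """Summed spectral power per band, under one normalisation mode.

    ``raw_power`` holds the unnormalised band sums; ``power`` is
    normalised per mode: ``per_session`` divides each band by the
    summed power of all analysed bands (unit sum), ``to_day1`` divides
    each band by the same band's raw power in the animal's day-1
    reference, ``none`` leaves raw sums.
    """

    bands: tuple[tuple[float, float], ...]
    power: np.ndarray
    raw_power: np.ndarray
    normalization: str
    day_index: int | None = None
    animal_id: str | None = None

    def band_fraction(self, lo_hz: float, hi_hz: float) -> float:
        """Fraction of total analysed power in the band [lo, hi)."""
        idx = self.bands.index((lo_hz, hi_hz))
        return float(self.raw_power[idx] / self.raw_power.sum())


def band_powers(
    x: TimeSeries,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    normalization: str = "per_session",
    day1: BandPowerSummary | None = None,
    window_s: float = 10.0,
    day_index: int | None = None,
    animal_id: str | None = None,
) -> BandPowerSummary:
    """Summed spectral power in each band with the chosen normalisation.

    Band membership is ``lo <= f < hi``. The input is expected to be
    band-passed to the analysis range already. ``to_day1`` requires the
    same animal's day-1 summary (raw powers) as reference.
    """
    if x.duration_s < 2.0:
        raise ValueError("band_powers needs at least 2 s of signal")
    if normalization not in ("per_session", "to_day1", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    f, pxx = spectral_power(x, window_s=window_s)
    df = f[1] - f[0]
    raw = np.array(
        [pxx[(f >= lo) & (f < hi)].sum() * df for lo, hi in bands]
    )
    if normalization == "per_session":
        power = raw / raw.sum() if raw.sum() > 0 else raw
    elif normalization == "to_day1":
        if day1 is None:
            raise ValueError("to_day1 normalization requires a registered day-1 reference")
        if tuple(day1.bands) != tuple(bands):
            raise ValueError("day-1 reference uses different bands")
        power = raw / day1.raw_power
    else:
        power = raw.copy()
    return BandPowerSummary(
        bands=tuple(bands),
        power=power,
        raw_power=raw,
        normalization=normalization,
        day_index=day_index,
        animal_id=animal_id,
    )


@dataclass
class EventDetectionConfig:
    """Seizure-like-event detector parameters.

    ``k_sd`` is the detection multiple of the day-1 baseline SD;
    ``combine`` selects whether the amplitude and fast-band criteria
    must hold simultaneously ("and", default) or either ("or").
    """

    k_sd: float = 3.0
    fast_band: tuple[float, float] = (71.0, 90.0)
    broadband: tuple[float, float] = (2.0, 90.0)
    min_dur_s: float = 1.0
    merge_gap_s: float = 0.5
    envelope_smooth_s: float = 0.1
    combine: str = "and"


@dataclass
class EventList:
    """Detected seizure-like events and the per-hour fast-activity burden."""

    events: list[tuple[float, float]]  # (onset_s, duration_s), sorted
    recording_length_s: float
    threshold_sd: float
    baseline_sd_uv: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = sorted(self.events)
        for (a0, d0), (a1, _) in zip(ev[:-1], ev[1:]):
            if a0 + d0 > a1:
                raise ValueError("events must be non-overlapping")
        self.events = ev

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def total_event_time_s(self) -> float:
        return float(sum(d for _, d in self.events))

    @property
    def fast_activity_sec_per_h(self) -> float:
        """Total event time normalised per recording hour."""
        return 3600.0 * self.total_event_time_s / self.recording_length_s


def _smoothed_envelope(values: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    env = np.abs(sps.hilbert(values))
    width = max(1, int(round(smooth_s * fs)))
    return uniform_filter1d(env, size=width, mode="nearest")


def detect_seizure_like_events(
    x: TimeSeries,
    day1_baseline: TimeSeries,
    cfg: EventDetectionConfig | None = None,
) -> EventList:
    """Detect high-amplitude fast-activity (seizure-like) events.

    Thresholds are anchored to the day-1 baseline: the amplitude
    criterion compares the smoothed analytic (Hilbert) envelope of the
    2–90 Hz band-passed signal against ``k_sd`` × SD of the band-passed
    day-1 baseline; the fast criterion compares the smoothed envelope
    of the 71–90 Hz band against ``k_sd`` × SD of the day-1 envelope in
    that band. Candidate runs separated by less than ``merge_gap_s``
    are merged, then runs shorter than ``min_dur_s`` are dropped.
    """
    cfg = cfg or EventDetectionConfig()
    if x.fs_hz != day1_baseline.fs_hz:
        raise ValueError(
            f"sampling-rate mismatch: signal {x.fs_hz} Hz vs baseline "
            f"{day1_baseline.fs_hz} Hz"
        )
    if day1_baseline.duration_s < 60.0:
        raise ValueError("day-1 baseline must be at least 60 s")
    fs = x.fs_hz
    lo, hi = cfg.broadband
    bb = bandpass_zero_phase(x, lo, hi)
    bb_base = bandpass_zero_phase(day1_baseline, lo, hi)
    sd_bb = float(np.std(bb_base.values))

    flo, fhi = cfg.fast_band
    fast = bandpass_zero_phase(x, flo, fhi)
    fast_base = bandpass_zero_phase(day1_baseline, flo, fhi)

    env_bb = _smoothed_envelope(bb.values, fs, cfg.envelope_smooth_s)
    env_fast = _smoothed_envelope(fast.values, fs, cfg.envelope_smooth_s)
    env_fast_base = _smoothed_envelope(fast_base.values, fs, cfg.envelope_smooth_s)
    sd_fast_env = float(np.std(env_fast_base))

    amp_crit = env_bb > cfg.k_sd * sd_bb
    fast_crit = env_fast > cfg.k_sd * sd_fast_env
    candidate = amp_crit & fast_crit if cfg.combine == "and" else amp_crit | fast_crit

    runs = _runs(candidate)
    runs = _merge_runs(runs, int(round(cfg.merge_gap_s * fs)))
    min_len = int(round(cfg.min_dur_s * fs))
    runs = [(a, b) for a, b in runs if (b - a) >= min_len]
    events = [(a / fs, (b - a) / fs) for a, b in runs]
    return EventList(
        events=events,
        recording_length_s=x.duration_s,
        threshold_sd=cfg.k_sd,
        baseline_sd_uv=sd_bb,
        provenance=dict(
            combine=cfg.combine,
            fast_band=cfg.fast_band,
            min_dur_s=cfg.min_dur_s,
            merge_gap_s=cfg.merge_gap_s,
            envelope_smooth_s=cfg.envelope_smooth_s,
            fast_envelope_sd=sd_fast_env,
        ),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < max_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]
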