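"""Laser-Doppler rCBF normalisation.

Doppler flow is recorded in arbitrary units; the analysis expresses it
as percent change from the mean of a pre-stimulation baseline window
(at least 15 min in the experimental protocol). Traces are not
detrended or filtered by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import TimeSeries

__all__ = ["normalize_rcbf", "epoch_average"]

MIN_BASELINE_S = 15 * 60.0


def normalize_rcbf(
    trace: TimeSeries,
    baseline_window_s: tuple[float, float],
    allow_short_baseline: bool = False,
) -> TimeSeries:
    """Percent change of a Doppler trace relative to a baseline window.

    Output is ``100 * (x - mean_b) / mean_b`` where ``mean_b`` is the
    mean over ``baseline_window_s`` (half-open, in seconds on the
    trace's own clock). The window must span at least 15 min unless
    ``allow_short_baseline`` is set; the baseline mean must be
    positive (arbitrary-unit flow).
    """
    if trace.unit != "doppler_au":
        raise ValueError(f"expected a doppler_au trace, got unit {trace.unit!r}")
    t0, t1 = baseline_window_s
    if not t1 > t0:
        raise ValueError("baseline window must have positive length")
    if (t1 - t0) < MIN_BASELINE_S and not allow_short_baseline:
        raise ValueError(
            f"baseline window of {t1 - t0:.0f} s is shorter than the 15-min "
            f"minimum ({MIN_BASELINE_S:.0f} s); pass allow_short_baseline=True "
            "to override"
        )
    t = trace.times_s
    sel = (t >= t0) & (t < t1)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    mean_b = float(trace.values[sel].mean())
    if mean_b <= 0:
        raise ValueError(f"baseline mean must be positive, got {mean_b:g} a.u.")
    pct = 100.0 * (trace.values - mean_b) / mean_b
    meta = dict(trace.meta)
    meta.update(baseline_window_s=(t0, t1), baseline_mean_au=mean_b)
    return TimeSeries(pct, fs_hz=trace.fs_hz, unit="percent", t0_s=trace.t0_s, meta=meta)


def epoch_average(
    trace: TimeSeries,
    schedule: list[tuple[float, float]],
    window_s: float = 60.0,
) -> pd.DataFrame:
    """Mean percent change within each stimulation-ON interval and the
    post-ON window that follows it.

    ``schedule`` is the expanded ON-interval list (seconds, on the
    trace's clock). Epochs that fall outside the trace are marked
    missing (NaN means), never dropped.
    """
    if trace.unit != "percent":
        raise ValueError("epoch_average expects a percent trace (normalise first)")
    t = trace.times_s
    rows = []
    for k, (on0, on1) in enumerate(schedule):
        on_sel = (t >= on0) & (t < on1)
        post_sel = (t >= on1) & (t < on1 + window_s)
        on_missing = not on_sel.any()
        post_missing = not post_sel.any()
        rows.append(
            dict(
                epoch=k,
                on_start_s=on0,
                on_end_s=on1,
                on_mean_pct=float(trace.values[on_sel].mean()) if not on_missing else np.nan,
                post_mean_pct=float(trace.values[post_sel].mean()) if not post_missing else np.nan,
                missing=on_missing,
            )
        )
    return pd.DataFrame(rows)
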