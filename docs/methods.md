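# Methods

This note documents the models, operators and numerical choices behind each
analysis stage, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Conventions

Pixel coordinates are 0-based, row-major `(row, col)` (row = y, col = x).
Time origin is the first sample/frame of each recording; stimulation
schedules are expressed relative to schedule start and aligned to recordings
via the `t0_s` metadata field. Time series are uniformly sampled with no
missing samples; gaps must be split into separate series.

## Stimulation schedule

`StimProtocol` represents (never drives) an SPG stimulation schedule:
`n_trains` trains of `sets_per_train` ON sets (`set_duration_s` each,
separated by `inter_set_gap_s`), with `off_time_s` of OFF time after each
train. The default acute protocol is 12 trains of two 60-s sets at 10 Hz
separated by 12 s, with 13.6 min OFF. A nominal `total_treatment_min` can be
stored as metadata; it is deliberately never recomputed from the per-train
parameters, because nominal totals quoted for such protocols are typically
rounded and need not be arithmetically consistent with the expansion
(12 × (2·60 s + 12 s + 13.6 min) = 189.6 min, not 180 min). `expand_schedule`
uses only the per-train parameters.

## Vessel morphometry

**Segmentation** is a fixed four-step pipeline per frame: median filter
(disk radius 2 px), local-mean adaptive threshold (51-px window; offset 2%
of the frame's dynamic range; polarity-aware, so bright- and dark-vessel
images are exactly symmetric under intensity inversion), morphological hole
filling, and removal of connected components below 64 px. A frame with zero
dynamic range yields an empty mask with a warning rather than an exception.
Local-mean thresholding was chosen as the simplest operator matching an
"adaptive threshold"; window and offset are configurable.

**Diameter** at a point is the contiguous foreground chord through the
vessel: the point snaps to the nearest skeleton pixel (ties broken by
smallest distance, then lowest row, then lowest column), the local tangent
is the principal direction of skeleton pixels within a ±3 px window, and
the mask is sampled along the perpendicular in 0.25-px steps. Sampling uses
bilinear interpolation with a 0.5 cut, which places the boundary half-way
between mask edge pixels; this removes the staircase bias that
nearest-neighbour sampling shows on oblique vessels (45° error drops from
1.25 px to 0.75 px on a 20-px synthetic ridge). The chord length times the
pixel size is the diameter. A chord through the skeleton was preferred to
2 × the distance transform because it directly counts pixels across the
vessel, the quantity of interest.

**Traces**: measurement points are operator inputs (five by default, as in
intravital practice); an optional helper proposes equidistant skeleton
points but is a convenience only. Each point is normalised to the mean of
its own baseline window before averaging across points
(`pct_change = 100·(d − d̄_baseline)/d̄_baseline`); normalise-then-average
was chosen over average-then-normalise so that a point on a locally thicker
segment does not dominate the group trace. Points lost in a frame are NaN
(never interpolated); a point missing in > 20% of frames is flagged in
provenance.

**Imaging conditions for recovery tests**: noiseless ridge checks use the
canonical 1 µm/px sampling where a 20-µm vessel spans 20 px. The noisy
dilation-recovery condition uses 0.5 µm/px (vessel ≈ 40 px across, matching
high-magnification EMCCD intravital imaging), because a binary mask
quantises each edge at ±0.5 px and at 1 µm/px that quantisation alone is
±2.5% of a 20-px diameter — the measurement would be resolution-limited
rather than noise-limited. Noise condition: additive Gaussian with
SD = contrast/5 (SNR 5).

## Angiography kinetics

Per-frame ROI mean intensities form the transit curve. Baseline is the mean
of the first 10 raw frames (pre-arrival window). The peak is located on the
curve after a centered 5-frame moving average (reflected edges) and then
refined to the raw maximum within one smoothing half-width: the smoothed
argmax alone is biased ~2 frames late whenever the decay is slower than the
rise, which is the normal bolus shape. Ties resolve to the earliest frame so
transit intervals are conservative and deterministic. A curve whose peak
does not exceed baseline is flagged "no bolus detected" and excluded from
transit metrics.

The peak-to-peak interval is venous minus arterial peak time (negative
values are reported with a warning, not clamped). Slope-to-max takes bolus
arrival as the first crossing of baseline + 10% of the baseline-to-peak
excursion on the smoothed curve (linearly interpolated between frames) and
divides the intensity gained from arrival to peak by the elapsed time.
Both metrics are invariant to constant intensity offsets and to time
shifts of the whole stack.

## Laser-Doppler rCBF

Doppler flow is in arbitrary units, so the only meaningful quantity is
percent change from baseline: `100·(x − x̄_b)/x̄_b` with `x̄_b` the mean over
the baseline window. The window must span at least 15 min (the experimental
protocol's minimum) unless explicitly overridden — synthetic tests use the
override. The baseline mean must be positive. Traces are not detrended or
filtered by default; optional smoothing is off by default. Epoch averaging
reports the mean % change within each expanded ON interval and within a
post-ON window; epochs outside the trace are marked missing, not dropped.

## ECoG

**Filtering**: 4th-order Butterworth band-pass (2–90 Hz default) applied
forward and backward (`sosfiltfilt`, odd-reflection padding), doubling the
effective order and cancelling phase. A 10 Hz tone passes with gain
≥ 0.95 and zero lag; a 0.5 Hz tone is attenuated below 0.1.

**Band power**: averaged periodogram over non-overlapping 10-s Hann windows,
power spectral density summed (× bin width) over each band with membership
`lo ≤ f < hi` for the five bands 2–4, 5–10, 11–45, 46–70, 71–90 Hz.
`per_session` normalisation divides each band by the summed power of the
five analysed bands, so the normalised powers sum to exactly 1 — division by
the full 2–90 Hz integral would leave the sum below 1 because the bands do
not tile the range (gaps at 4–5, 10–11, 45–46, 70–71 Hz). `to_day1` divides
each band by the same band's raw power in the animal's registered day-1
summary. Integrated 2–90 Hz power tracks the time-domain variance of the
band-passed signal within 5% (Parseval consistency).

**Seizure-like events**: thresholds anchor to the day-1 baseline. The
amplitude criterion compares the smoothed (0.1-s moving average) Hilbert
envelope of the 2–90 Hz signal against `k_sd` (default 3) × SD of the
band-passed day-1 baseline; the fast-activity criterion compares the
smoothed envelope of the 71–90 Hz band against `k_sd` × SD of the day-1
envelope in that band. The envelope — rather than rectified samples — is
used for the amplitude test because a sample-wise comparison of an
oscillatory signal against an amplitude threshold holds only ~60% of the
time even inside a genuine event (the carrier crosses zero), fragmenting
events and, after gap-merging, chaining background outliers into false
detections. The two criteria are combined with logical AND (an OR mode
exists behind a config flag for sensitivity analysis). Candidate runs
separated by less than 0.5 s are merged, then runs shorter than 1 s are
dropped — merging must precede the duration filter, otherwise every
sub-second fragment would be deleted before it could merge. `min_dur_s = 1`
and `merge_gap_s = 0.5` reflect the seconds-long character of these events.
Burden is `3600·Σ durations / recording length` (s/h). Detection is
equivariant under common amplitude scaling of signal and baseline.

Known detectability limitation: the 2–90 Hz zero-phase filter attenuates
carriers near the 90 Hz edge (filtfilt squares the single-pass Butterworth
gain, ≈ 0.5 amplitude at 88–90 Hz), so a 5×SD burst at the extreme top of
the fast band can fall below the 3×SD threshold. Recovery tests therefore
use the mid-band 80 Hz carrier as their study condition; detection
sensitivity is reported for that condition only. Onsets carry a systematic
delay of ≈ 0.3–0.45 s (threshold crossing on the burst's rise) — within the
0.5-s matching tolerance but not zero.

## Histology

Evans-blue: the blue channel of the RGB photograph is averaged over the
whole treated-hemisphere mask (not only supra-threshold pixels), and
`pct_blue_pixels` counts pixels strictly above a caller-supplied fixed
threshold. The threshold has **no default** — it is a required input,
recorded in provenance, because no principled universal cutoff exists for
uncalibrated photographs. Hemisphere and cortex masks are inputs (drawn or
generated), never auto-segmented.

Lesion volumetry: per-section loss is `100·(1 − ipsi px / contra px)`; the
aggregate divides summed ipsilateral by summed contralateral counts, i.e.
area-weighted across sections. Equal section thickness (40 µm) justifies
the area sum as the volume proxy. The aggregate is recomputed from the
per-section counts as a consistency check and always lies between the
per-section extremes.

## Group statistics

Mann-Whitney U (two-sided) with the U statistic for the first sample
(pairs with x > y, ties counted half). With `min(n, m) ≤ 8` and no ties the
p-value comes from the exact permutation distribution; otherwise the normal
approximation with midrank tie correction and continuity correction is
used; all-tied samples return p = 1 (degenerate). Two-sided p doubles the
smaller one-sided tail, capped at 1. The computation is delegated to
scipy's implementation behind this interface; the test suite cross-checks
it against an independent full-enumeration oracle, exhaustively for every
tie-free rank arrangement with n, m ≤ 6. Group summaries report n, mean,
and SEM (sample SD with n−1 denominator over √n). No multiple-testing
correction is applied, matching the single-comparison design.

## Synthetic data: what it emulates, what it does not

All generators are deterministic given (spec, seed), and every generator
returns a truth table sufficient to score the downstream estimator without
re-deriving truth from the rendered data.

- **Vessel stacks** render each vessel as a ridge with rectangular (top-hat)
  cross-section of the true local width and a 1-px anti-aliased border, so
  the true diameter is unambiguous; Gaussian-profile vessels are not used
  for recovery scoring because the diameter of a Gaussian ridge is
  convention-dependent. Additive Gaussian noise only; no motion, no focus
  drift, no branching topology.
- **Angiography stacks** drive each disjoint ROI with
  baseline → ramp-to-peak (linear or gamma-variate) → exponential decay;
  additive Gaussian pixel noise; no physiological pulsatility, no dye
  recirculation.
- **ECoG** shapes white noise to a 1/f^α spectrum with support restricted
  to 2–90 Hz (α = 1, RMS 50 µV by default — plausible for rodent epidural
  recordings), then adds Tukey-windowed (α = 0.25) sinusoidal bursts whose
  envelope peaks at `amplitude_multiple` × background SD, carrier drawn
  uniformly from the event's band (or fixed when both edges coincide).
  Real seizure-like events are broadband and non-stationary; a single
  carrier is the cleanest construction for which "true onset/duration" is
  well defined.
- **Evans-blue images** raise the blue channel over a compact blob
  occupying exactly the programmed fraction of treated-hemisphere pixels;
  **coronal sections** give the ipsilateral cortex mask exactly
  `round((1 − loss)·A)` of the contralateral area A per section.

Passing recovery tests therefore demonstrates that the estimators are
correct and unbiased under these idealised conditions; they do not
establish robustness to motion artifacts, staining variability, electrode
drift, or other features of real recordings that the generators omit.

## Study conditions and problem sizes

Recovery tests and the acceptance script run at desk scale: 12-frame
diameter stacks (160×160 px), 8-s angiography stacks at 30 fps (240
frames), a 1-h event-recovery ECoG record plus 10 × 30 min of event-free
background for the false-positive rate, 6 coronal sections, and a
four-group demo pipeline with 4 animals per group and 3-min ECoG sessions.
Tolerances: noiseless diameter ±1 px; noisy +12% dilation ±2 percentage
points; peak separation ±1 frame; ramp slope ±5%; tone band concentration
≥ 95%; flat-spectrum band proportionality ±10%; Parseval ±5%; ≥ 9/10
events with onsets ±0.5 s and < 1 false event/h; Evans-blue fraction
±1 point; aggregate cortical loss ±0.5 points; exact Mann-Whitney p equal
to enumeration; byte-identical pipeline reruns.
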