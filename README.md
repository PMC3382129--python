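# sphenostim

Quantification pipeline for experiments on sphenopalatine-ganglion (SPG)
stimulation in the rat photothrombotic-stroke model. The package
reimplements, as tested and reusable code, the full measurement stack such a
study needs:

- **vessel morphometry** — segment pial vessels in intravital image stacks
  (median denoise → local-mean adaptive threshold → hole filling → small-object
  removal) and track vessel diameter at operator-chosen points as the
  perpendicular pixel chord through the vessel skeleton, expressed as
  % change of a pre-stimulation baseline;
- **angiography kinetics** — ROI intensity curves from 30 fps fluorescent
  angiography, with the arterial–venous peak-to-peak transit interval and the
  slope-to-max (mean rise rate from bolus arrival, at 10% of the
  baseline-to-peak excursion, to the peak);
- **laser-Doppler rCBF** — normalisation of arbitrary-unit flow traces to
  % change from a pre-stimulation baseline (≥ 15 min by protocol), plus
  per-stimulation-epoch averages over an expanded train/set schedule;
- **ECoG spectral analysis** — zero-phase 2–90 Hz Butterworth band-pass,
  Hann-taper averaged periodogram with band power summed over
  2–4, 5–10, 11–45, 46–70 and 71–90 Hz (normalised per session or to the
  animal's day-1 recording), and seizure-like-event detection: episodes whose
  amplitude envelope exceeds 3 × SD of the day-1 baseline with concurrent
  71–90 Hz fast activity, reported as fast-activity burden in s/h;
- **histology** — Evans-blue blood–brain-barrier quantification (mean
  blue-channel intensity and % supra-threshold blue pixels in the treated
  hemisphere) and cortical-volume loss from serial coronal sections,
  100·(1 − Σ ipsi px / Σ contra px);
- **group statistics** — mean ± SEM summaries and two-sided Mann-Whitney U
  tests (exact permutation p for small tie-free samples, tie-corrected
  normal approximation otherwise).

No raw recordings from such experiments are publicly deposited, so the
package ships a first-class **synthetic-data module**: seeded generators for
every input modality (vessel ridge stacks, bolus-transit stacks, 1/f ECoG
with injected high-amplitude fast bursts, Evans-blue photographs, coronal
sections) with programmed ground truth, giving every analysis stage a
parameter-recovery test.

## Worked example

Generate a noisy diameter-imaging stack with a programmed +12% dilation
(frames 4–11) and recover it:

```python
import numpy as np
from sphenostim.synthetic_data import StackGeometry, VesselSpec, make_vessel_stack
from sphenostim.vessel_morphometry import diameter_timeseries

geom = StackGeometry(shape=(160, 160), pixel_size_um=0.5,
                     frame_interval_s=2.0, n_frames=12)
diam = np.concatenate([np.full(4, 20.0), np.full(8, 22.4)])   # +12% dilation
spec = VesselSpec(centerline=[(80.25, 10.0), (80.25, 150.0)],
                  diameter_um=diam, noise_sd=20.0)             # SNR 5
stack, truth = make_vessel_stack(spec, geom, seed=1)

points = truth[truth.frame == 0][["row", "col"]].to_numpy()
trace = diameter_timeseries(stack, points, baseline_window=(0, 4))
print("baseline diameter (um):", np.round(trace.provenance["baseline_um"], 2))
print("point-averaged % change:", np.round(trace.mean_pct_change, 2))
print("plateau mean: %.2f %%" % np.mean(trace.mean_pct_change[4:]))
```

prints

```
baseline diameter (um): [20.   20.   20.   19.75 20.  ]
point-averaged % change: [ 0.25 -0.25 -0.25  0.25 12.78 11.78 12.28 11.78 11.28 12.78 10.78 12.28]
plateau mean: 11.97 %
```

Each of the five measurement points is normalised to its own baseline-window
mean and the per-frame traces are averaged, so the recovered plateau
(11.97%) sits within measurement noise of the programmed +12% dilation.

The same stages are available from the shell via the `sphenostim` CLI
(`synth`, `vessel`, `angio`, `doppler`, `ecog`, `histo`, `stats`, `run`);
`sphenostim run --config examples/demo_config.yaml --out results/` executes
the full simulate → analyse → compare pipeline for the four chronic-study
groups (Sham, RB, RB-SPG-15min, RB-SPG-24h) and writes `bands.csv`,
`events.csv`, `lesion.csv`, `stats.csv` plus a provenance manifest. The
same config and seed always reproduce byte-identical CSVs.

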