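# ventriflow

Functional phenotyping of engineered cardiac ventricles — miniature,
beating tissue constructs (hiPSC-derived cardiomyocytes on a hemispherical
elastomer membrane) whose contractions displace culture medium through a
flow sensor. `ventriflow` turns the raw recordings of such a system into
the standard pump-function readouts, for tissue engineers and
cardiac-physiology labs running heart-on-a-chip experiments:

* **Beat analytics from pulsatile flow traces** — beat frequency *f* (bpm),
  per-beat stroke volume *SV* (nL, the maximum of the cumulative displaced
  volume V(t) = ∫ q dt within a beat), theoretical cardiac output
  *CO = f · SV* (nL/min), and maximum volume flow (µL/min).
* **Displacement reconstruction from rectified optical flow** — commercial
  motion-tracking software reports only |motion| per frame; `ventriflow`
  recovers signed displacement by integrating with one sign reversal per
  beat, placed where forward and backward rectified integrals balance, so
  the tissue returns to its point of origin after every beat.
* **Drug-response normalization** — paired pre/post-incubation recordings
  (e.g. isoproterenol, carbachol) expressed as per-ventricle post/pre
  ratios and percent changes.
* **ΔΔCt fold changes** — housekeeping-normalized relative gene expression,
  fold = 2^−ΔΔCt.
* **A synthetic-data generator** — pulsatile flow with analytically known
  rate/stroke volume (half-sine ejection and refill lobes that conserve
  volume per beat), rectified motion traces, speckle-textured beating
  videos, and Ct tables with prescribed fold changes; every analysis stage
  is validated against this ground truth.

## Worked example

```python
from dataclasses import replace
from ventriflow import (VentricleSimParams, ejection_peak_flow,
                        generate_flow_trace, analyze_recording)

p = VentricleSimParams(beat_rate=80, stroke_volume=13.8, duration=60, seed=2)
p = replace(p, noise_sd=0.05 * ejection_peak_flow(p))   # 5% sensor noise

trace = generate_flow_trace(p)          # 60 s at 50 Hz, ground truth known
metrics, beat_table = analyze_recording(trace)
print(metrics)
```

```
RecordingMetrics(frequency=80.01, mean_stroke_volume=13.81,
                 theoretical_cardiac_output=1104.9,
                 max_volume_flow=6.95, n_beats=80)
```

The pipeline (running-median detrend → threshold-crossing beat detection
with a refractory period → per-beat trapezoid volume integration) hands
back the injected 80 bpm within 0.02% and the injected 13.8 nL stroke
volume within 0.1% despite the noise; cardiac output is exactly
frequency × mean stroke volume (1104.9 nL/min ≈ 1.1 µL/min). `beat_table`
lists onset time, period, stroke volume and peak flow per beat.

The same works from the shell:

```sh
ventriflow simulate --config sim.yaml --out-dir run/
ventriflow analyze run/flow.csv --out-metrics run/metrics.json
ventriflow drug-response pre.json post.json --out response.json
ventriflow motion video.tif --fps 30 --frame-offset 6
ventriflow qpcr ct.csv --reference-group day0 --test-group ventricle
```

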