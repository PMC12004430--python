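# Methods

## The measurement model

An engineered ventricle is a closed, medium-filled chamber whose
cardiomyocyte-covered membrane contracts periodically, pushing medium
through a flow sensor. The sensor reports signed volumetric flow q(t)
(µL/min). One beat consists of an ejection phase (q > 0), a refill phase
(q < 0) and quiescence; because the chamber is closed, the net displaced
volume per beat is zero. The four functional readouts are:

* beat frequency f (bpm), from beat onsets: f = 60·(n−1)/(t_last − t_first);
* stroke volume SV (nL): per beat, the maximum of the cumulative displaced
  volume V(t) = ∫ q dτ measured from the beat onset (robust to asymmetric
  refill; equal to the positive-lobe integral for symmetric beats);
* theoretical cardiac output CO = f × mean SV (nL/min), an identity the
  code maintains exactly;
* maximum volume flow: the largest instantaneous detrended flow across
  detected beats.

Units are fixed at s, µL/min and nL; the single conversion factor
1000/60 nL per (µL/min·s) lives in `ventriflow.units`.

## Synthetic flow generator

`generate_flow_trace` builds each beat from a positive half-sine ejection
lobe of duration d_e = systole_fraction·T and a negative half-sine refill
lobe of duration d_r = refill_fraction·T, followed by quiescence. The
ejection peak is Q = SV·π·60/(2·d_e·1000) µL/min so the analytic lobe
integral equals SV; the refill lobe integrates to −SV. Beat periods are
lognormal with a prescribed coefficient of variation (so they stay
positive); sensor realism is additive white Gaussian noise on the flow and
a linear drift term. Defaults: 50 Hz sampling (≥ 10 samples per ejection
lobe up to ~100 bpm), systole fraction 0.3, refill fraction 0.5, no jitter,
no noise, no drift — the regular-beating regime the analyzed recordings
show; noise and jitter are switched on explicitly where a test needs them.

Because point-sampled half-sines do not integrate to exactly ±SV under the
trapezoid rule (the two lobes discretize with different O(h²) errors), the
generator rescales each fully sampled lobe so its *discrete* trapezoid
integral is exactly ±SV. Volume conservation per beat then holds to float
round-off at any sample rate, at the cost of the sampled peak exceeding
the closed-form peak by the O(h²) trapezoid factor (~0.4% at 50 Hz, ~1e-5
at 1 kHz).

What the generator does not emulate: flow-sensor transfer functions and
quantization, bubble artifacts, arrhythmic or multi-phase beats, slow
amplitude rundown. Passing the recovery tests therefore demonstrates
correctness of the analysis chain under the stated signal model, not
robustness to every failure mode of real recordings.

## Flow analysis pipeline

1. **Detrend** — subtract a running-median baseline (default window 5 s,
   ≥ 2 of the longest expected periods). The raw sliding median jumps
   between sample quantiles as beats slide through the window, leaving
   ripple at the beat frequency, so the baseline is additionally smoothed
   by a moving average over ~1/5 of the window; constants and linear ramps
   still map to themselves and are removed.
2. **Detect beats** — onsets are upward crossings of
   θ = threshold_frac × P95(|q|) (default 0.2; the 95th percentile resists
   outlier spikes), with a refractory time of 60/max_rate between onsets
   and inter-onset gaps longer than 60/min_rate discarded as non-beats.
   Detection runs on a zero-phase moving-average copy of the signal
   (default 0.1 s): without it, noise at 10% of the ejection peak sits ~2
   standard deviations below θ and spawns spurious onsets during
   quiescence. The smoothing is centered, so onset times shift uniformly
   and the onset-span frequency is unbiased; all measurements are taken on
   the unsmoothed detrended trace.
3. **Per-beat measures** — trapezoid cumulative volume from the onset;
   SV = max V, peak flow = max q, period = onset-to-next-onset. For
   complete beats the pipeline enforces the volume-closure boundary
   condition of the closed chamber (V(end) → 0 via ramp subtraction),
   which cancels the small residual baseline offset a median detrend
   leaves on noisy data; bare `beat_measures` keeps the uncorrected
   definition. The trailing incomplete beat contributes to SV only if its
   volume maximum precedes the trace end, and never to frequency.
4. **Summary** — frequency from the onset span (well-behaved for partial
   windows), mean SV, CO as the exact product, max volume flow as the
   global maximum across beats (a recording-level maximum, matching how a
   single peak value is reported per measurement).

Measured recovery under the default conditions (60 s, 50 Hz, fixed seeds):
frequency within 0.4% at 10% peak-relative noise; mean SV within 1.5% at
5% noise; worst case over the 40–120 bpm × 5–50 nL × {0, 10%} noise grid:
0.14% (frequency) and 3% (SV).

## Displacement from rectified optical flow

Dense optical flow of a beating tissue is estimated with the TV-L1
estimator (coarse-to-fine, accurate to ≤10% for rigid shifts of a few px;
default frame offset 6), and the per-pair magnitude is the spatial mean of
per-pixel vector norms over the full frame (no ROI). Magnitudes obtained
at frame offset k are displacements per k-frame interval, so integration
uses an effective step of 1/k frames to stay in px.

The magnitude is non-negative; the sign is reconstructed per beat by
flipping it once, at the sample r minimizing |∫_onset^r m − ∫_r^end m|
(ties toward the smaller index — contraction first). The implementation
uses cumulative sums and agrees exactly with exhaustive search over all
candidate indices. On discrete, noisy data the end-of-beat displacement is
not exactly zero; the residual is removed by subtracting a linear ramp
across the beat — the minimal correction preserving the reversal-point
amplitude to first order. Beats whose pre-correction residual exceeds 10%
of the amplitude are flagged as possibly multi-phase (one reversal per
beat is assumed); samples outside any beat are integrated with sign +1 and
counted in metadata. For a return-to-origin excursion of amplitude A the
rectified path length is 2A, giving the amplitude identity
(amplitude = rectified integral / 2) used throughout the tests.

Beat segmentation on magnitude traces reuses the flow-trace detector; a
beat's magnitude is double-humped (contraction and relaxation), so the
default smoothing is wider (0.15 s) and the refractory time must exceed
the intra-beat gap for the chosen rate band.

## Drug response and ΔΔCt

Drug effects are paired per ventricle: ratio = post/pre and
percent = 100·(ratio − 1) per metric, computed only for positive
baselines. No cross-ventricle pooling or dose–response modeling is done.

ΔΔCt: replicate Ct values are averaged per (group, gene) before
differencing (the common convention); ΔCt normalizes to the housekeeping
gene within group, ΔΔCt differences test against reference, and
fold = 2^−ΔΔCt. Replicate scatter is propagated to the ΔΔCt (= log2-fold)
scale by quadrature over the four standard errors. Genes absent from one
group get a distinct not-detected status, never a numeric fold. No
primer-efficiency correction and no multi-housekeeping geometric means.

## Numerical and design choices

* Integration is trapezoid throughout; SV agrees with a 10× oversampled
  Riemann oracle within 0.5%.
* Lognormal period jitter keeps periods positive at any CV.
* Reversal-index tie-breaks go to the smallest index; reciprocity of fold
  changes is exact on the ΔΔCt scale (negation), and exact to one ulp on
  the fold scale.
* Degenerate inputs: an all-zero trace detects no beats (empty list, not
  an error); summaries require ≥ 2 beats and say how many were found;
  all-zero beats in motion traces are skipped with zero amplitude.
* File parsing is dialect-driven (delimiter, decimal mark, column
  names/indices, units, header rows) with conversion to canonical units at
  the boundary; irregular timestamps are resampled by linear interpolation
  when jitter exceeds 1% of the median interval.
* Problem sizes in tests and the acceptance script: 60 s recordings at
  50 Hz (3000 samples), 30 s for the recovery grid, 64×64 px videos of
  ≤ 60 frames — small enough to run the whole suite in seconds while
  keeping ≥ 10 samples per ejection lobe and ≥ 2 px of texture gradient
  per speckle.

## Known limitations

* Beat detection assumes a dominant positive ejection lobe; biphasic or
  negative-first waveforms would need a different onset rule.
* The sign-reversal reconstruction assumes exactly one contraction–
  relaxation excursion per beat; multi-phase beats are only flagged.
* The magnitude aggregation averages over the full frame; a stationary
  background dilutes the amplitude scale (relative comparisons remain
  valid).
* The vendor CSV dialect defaults are declared, not validated against an
  actual sensor-viewer export.
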