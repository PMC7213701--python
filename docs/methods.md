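# Methods

## The model

`fetalqt` estimates the end of the T wave in a fetal ECG beat from the RR
interval alone. Ventricular repolarization is treated as the discharge of a
capacitor whose time constant is tied to the instantaneous heart rate: with
`t` and `RR` in milliseconds, each beat carries the dimensionless curve

```
R(t) = 100 · exp(−2π t / RR),      0 ≤ t < RR,
```

starting at 100 at the R peak. A band constant

```
k = | f( mean(R), x ) − 6π x² |,      x = 1/RR  (RR in seconds),
```

defines an open value band `(k − 0.5, k + 1)` on the curve; the estimated
T-end offset from the R peak is the median time of the grid samples whose
curve value falls strictly inside that band. QT is the Q→R offset plus the
T-end offset, and QTc applies one of the four standard corrections
(Fridericia `QT/RR_s^{1/3}` by default; Bazett, Framingham and Hodges are
also registered; all four leave QT unchanged at RR = 1 s).

### The two readings of the band constant

The defining expression for `k` is typographically ambiguous: `mean(R) x`
can be a quotient (`mean/x`) or a product (`mean·x`). Both readings are
registered in `core_model.BAND_INTERPRETATIONS` (`"quotient"`, the default,
and `"product"`), additional readings can be registered at run time, and
`calibrate_interpretations` / the `calibrate-band` CLI command sweep every
registered reading over RR 330–600 ms and report the fraction of estimated
T-ends inside the physiological 170–330 ms window (the interval in which
aortic-valve closure is observed after the R peak in fetuses).

Neither stock reading is plausible: for RR 330–600 ms the quotient reading
yields T-ends of roughly 0–80 ms after the R peak (and for RR below ≈ 421 ms
its band lies entirely above the curve's ceiling of 100, so no estimate
exists at all), while the product reading yields roughly 25–130 ms. Both
in-window fractions are therefore 0. The package reports this honestly
rather than substituting a "corrected" formula; estimates outside the
window carry a `t_end_outside_plausibility_window` flag but are returned.

### Numerical choices in the core

- **Curve grid.** `dt_ms` defaults to 1 ms (the recordings the method
  targets are sampled at 1 kHz); the grid is `t = 0, dt, …  < RR`.
- **Curve mean.** `RepolarizationCurve.mean()` is the trapezoidal
  quadrature of the curve over the full beat `[0, RR]`, closed with the
  analytic endpoint value `100·e^{−2π}`. Its error is O(dt²) (≲ 0.005% of
  the closed form `(100/2π)(1 − e^{−2π}) ≈ 15.886` at dt = 1 ms), so the
  band constant does not depend on the grid resolution. The plain sample
  mean (available as `sample_mean()`) carries a half-sample bias
  `(100 − R(RR))·dt/(2RR)` — about 1% at RR = 300 ms — which would leak
  grid resolution into `k`.
- **Median of the band.** Strict inequalities on both band edges, median
  taken over the time offsets of the selected samples; an even count yields
  the midpoint of the two central grid times. For a strictly decreasing
  curve this coincides with the time of the median value up to grid
  resolution.
- **Degenerate bands.** An empty band, or a band whose median time is ≤ 0
  (the band covering only the R peak itself), raises a no-estimate error
  identifying the beat; batch estimation logs these beats and continues.
- **Physiological bounds.** Beats with RR outside 200–1200 ms are excluded
  (fetal rates in the target population are roughly 108–181 bpm), and a
  beat whose QT would reach or exceed its RR is rejected as implausible
  rather than silently returned.
- **Rounding.** All interval arithmetic is unrounded; rounding to whole
  milliseconds happens only in reporting layers.

## Signal processing

- **Denoising.** 10-level discrete wavelet decomposition with Daubechies
  db4 and symmetric extension. Detail levels 1–4 (≈ 63–500 Hz at 1 kHz) and
  7–10 (≈ 1–7.8 Hz) are zeroed; the level-10 approximation is zeroed too,
  since keeping it would retain exactly the sub-1 Hz drift that baseline
  removal exists to eliminate. Level indices, not nominal band edges, are
  normative (dyadic bands only approximate the printed frequencies).
  Records shorter than `(filter_len − 1)·2^levels` samples (7168 for db4 at
  10 levels) are rejected with the minimum named. The zeroing is a linear
  projection: reapplying it changes the interior of the record by < 1e−9,
  with boundary transients confined to about one filter support per level
  (≈ 3.5 k samples each side at 1 kHz).
- **R-peak detection.** Adaptive threshold on the rectified, median-centred
  signal: initialized at 0.5 × max(99.5th percentile, half the global
  maximum), then tracking 0.5 × the median amplitude of the trailing 8
  accepted peaks, with a 200 ms refractory period (covers fetal rates up to
  ≈ 300 bpm). A flat or sub-threshold record returns an empty annotation
  set with a warning, not an exception.
- **Q location.** Minimum sample in a 60 ms window before each R peak (the
  window length is a package default; it is not fixed by the method's
  description), ties broken toward R; truncated windows and windows with no
  interior minimum are flagged.
- **Tangent T-end (reference method).** T apex = largest |amplitude −
  baseline| in a 120–400 ms window after R, clipped 50 ms short of the next
  R; steepest point sought on the 80 ms after the apex (bounding the limb
  keeps the next beat's Q descent out of the search); tangent slope fit by
  least squares over ±5 ms; T-end = intersection of that tangent with the
  isoelectric baseline. The baseline defaults to the mode of the record's
  amplitude histogram: at fetal rates the waves occupy the majority of each
  beat, so median-based estimates (also available in config) are biased
  upward. Beats without an apex of at least 0.05 amplitude units raise a
  no-estimate error, mirroring the exclusion of unclear T waves.

## Agreement statistics

Bland–Altman bias, sd (denominator n − 1), limits at ±1.96·sd, and the
percentage of pairs strictly inside the limits; differences are always
oriented estimate − reference. Zero-variance series collapse the limits
onto the bias and report 100% within, flagged. `rmse² = bias² +
((n−1)/n)·sd²` holds by construction. Group summaries mirror the clinical
comparison-table layout (count, mean ± sd of RR/HR/QT/QTc for estimate and
reference, RMSE columns). Trends against gestational age use OLS with
*prediction* (not confidence-of-mean) intervals, because individual
subjects are classified against the bounds; a point strictly outside its
interval is flagged.

## The synthetic generator

Each beat is a sum of Gaussian waves on a flat baseline: P (amp 0.1,
−90 ms, width 12 ms), Q (−0.1, −35 ms, 5 ms), R (1.0, 0, 7 ms), S (−0.2,
+22 ms, 6 ms), T (0.2, width 16 ms). Amplitudes reflect the low T/P-to-R
ratio of fetal ECG. Per-beat RR comes from a per-beat heart rate
N(140, 5²) bpm by default (the normal fetal cohort the estimator targets
runs at 142 ± 9 bpm), rounded to whole samples at 1 kHz so truth fiducials
are exact grid points. True QT follows `QT = 325 · RR_s^{1/3}` ms, making
the Fridericia-corrected truth constant at 325 ms; the T centre is placed
so that the **true T-end — defined as the T-Gaussian centre + 2.5 widths, a
documented artifact convention** — equals QT minus the 35 ms Q offset.
Optional additive white noise and a baseline sinusoid emulate the noise
floor and respiration drift; a surrogate reference T-end series is truth +
seeded Gaussian jitter. One integer seed drives everything; identical
config + seed reproduces samples and truth bit for bit.

What the generator does **not** emulate: maternal-fetal signal mixtures and
their separation residue, electrode motion artifacts, waveform morphology
variation (notched T waves, biphasic T), overlap of T and P at extreme
rates, or Doppler-derived reference timing noise structure. Passing tests
on this generator therefore demonstrate correctness of the algorithms under
idealized morphology, not clinical performance on abdominal recordings.

On clean generated records the tangent rule's geometry implies a small
systematic offset: for a Gaussian T of width w, the tangent at the steepest
descent point meets the baseline at centre + 2w, while the truth convention
puts T-end at centre + 2.5w, so the expected bias is ≈ −0.5w (−8 ms at
w = 16 ms), within the ±10 ms recovery property the tests assert.

## Problem sizes

The test suite and the acceptance script use 150–500-beat records (1–3.5
minutes of 1 kHz signal), 1000 random RR draws for the estimator-vs-scan
equivalence, 20 × 17,227 Gaussian pairs for the Bland–Altman construction,
and a 271-point RR sweep for the calibration report; these sizes give
sampling error well below every asserted margin.

## Known limitations

- The band-constant ambiguity is unresolved by construction: the package
  exposes both readings and the calibration report, and the default
  (quotient) produces implausibly early T-ends — users validating against
  clinical references should inspect `calibrate-band` output first.
- WFDB-format records are not read natively; records travel as two-column
  CSV (time_s, amplitude).
- The tangent method assumes a single-apex T wave; biphasic T waves are
  estimated from their dominant lobe.
- The R detector assumes the R wave dominates the rectified signal; deep
  pathological Q/S complexes of comparable amplitude would need a
  polarity-aware detector.
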