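# Methods

This note documents the model behind `eogclean`, the tunable parameters and
their defaults, what the semi-simulated generator does and does not emulate,
and the numerical decisions made where the published procedure leaves the
implementation open.

## Signal model and pipeline

A recording is a matrix `x` (channels × samples, µV) assumed to be an
instantaneous linear mixture `x = A s` of statistically independent,
non-Gaussian sources with an invertible mixing matrix.  Ocular activity
enters as one or two additional sources — a vertical one (blinks) and a
horizontal one (saccades) — whose scalp projections are strongest over the
forehead and decay with distance from the eyes.

The pipeline preprocesses (band-pass, average reference), unmixes with
Infomax ICA, flags ocular components, finds their peaks, and corrects each
flagged component only inside 1-s windows around the peaks by keeping the
high-frequency wavelet bands; full rejection is the fallback when windows
cover more than 60 % of a component.  Two baselines share the same
identification stage: `wica` threshold-cleans the whole component, `icarej`
zeroes it.

## Tunable parameters

| key | default | meaning |
| --- | --- | --- |
| `filter.low_hz` / `filter.high_hz` | 1 / 47 Hz | pass band of the zero-phase Butterworth filter |
| `filter.order` | 4 | one-way design order (effective magnitude order 8 after the forward–backward pass) |
| `ica.max_iter` / `ica.tol` | 512 / 1e-6 | Infomax sweep limit and weight-change stopping criterion |
| `identify.min_abs_corr` | 0.5 | confirmatory frontal-correlation gate for fence outliers |
| `peaks.amp_factor` | 3 | amplitude rule `|Y| > amp_factor * mean(|Y|)` |
| `peaks.min_separation_s` | 0.5 s | minimum spacing between kept peaks |
| `peaks.tie_break` | `largest` | which peak survives inside a 0.5-s neighbourhood (see below) |
| `windows.width_s` | 1.0 s | correction-window length |
| `windows.reject_fraction` | 0.60 | coverage above which the whole component is rejected (strict `>`) |
| `wavelet.basis` / `wavelet.levels` | sym4 / 5 | decomposition basis and depth; `levels: auto` sets `ceil(log2(fs/6.25))` so the removed band tracks ≈0–6.25 Hz at any sampling rate |
| `wavelet.keep` | D1, D2, D3 | detail bands retained inside windows (≈12.5–100 Hz at 200 Hz) |
| `wavelet.crossfade_s` | 0.01 s | linear blend at window edges |
| `wica.threshold_scale` | 1.0 | multiplier on the universal threshold of the wICA baseline |

## Numerical choices

**Zero-phase filtering.**  "Zero-phase 4th order" is interpreted as a
4th-order design applied forward and backward (squaring the magnitude
response); edges use odd-symmetric extension so start/end transients do not
masquerade as peaks.

**ICA.**  Infomax with the logistic nonlinearity and natural-gradient
updates; data are PCA-whitened first, dropping exactly one dimension for
average-referenced input.  The learning rate adapts per sweep — +5 % while
successive updates stay within 60°, ×0.7 when they oscillate, capped at
0.03 — because a fixed or decay-only schedule left the rotation near its
whitening initialization on realistic (weakly super-Gaussian, temporally
correlated) sources; the adaptive schedule reaches the separation plateau
measured against ground-truth mixing and then settles below the stopping
tolerance.  Components are scaled to unit variance with the strongest
mixing weight positive, so downstream peak detection and tests are
reproducible.  Everything is deterministic given the seed.

**Wavelet cascade.**  The multilevel transform is built from PyWavelets'
single-level periodized transform; an odd-length stage is extended by one
zero sample (an isometry) before splitting, which makes perfect
reconstruction, linearity *and* energy conservation exact for any input
length — the more common duplicate-last-sample convention conserves energy
only approximately.  Window segments are reflect-padded before the cascade
so a 1-s window supports 5 levels without boundary artifacts, and a 10-ms
linear crossfade inside each window edge prevents splice discontinuities
from ringing through the inverse ICA.  Samples outside windows are copied
through untouched.

**Peak tie-break.**  The spacing rule does not say which of two close peaks
survives.  The default keeps the **largest** peak in each 0.5-s
neighbourhood: the band-pass filter gives every blink negative side lobes
about 0.25 s from the apex that also clear the amplitude rule, and an
earliest-first scan would keep a side lobe and drop the apex, shifting
detected times by ~0.25 s.  An `earliest` mode is available.

**λ (artifact-removal percentage).**  The definition mixes a lag-1
autocorrelation (reference term) with two cross-correlations; it is applied
literally.  It is only meaningful where contamination actually pulled
`corr(pure, contam)` below the reference: when `R_ref − R_contam < 0.02`
the ratio is numerically meaningless (and rewards distortion), so the
channel is reported as NaN and excluded from channel averages.

**ΔSNR** is capped at ±120 dB for exact-recovery degenerate cases.  **MSC**
uses Welch averaging with 2-s Hann segments and 50 % overlap (at least two
segments required).  **Sensitivity** matches detections to annotations
greedily, one-to-one, within ±100 ms.

**wICA baseline.**  The original thresholding rule is not fully specified
here; the baseline zeroes every coefficient above the universal threshold
`sqrt(2 ln N) · median(|D1|)/0.6745` (scale configurable) over the full
component length.  It is a baseline-approximate stand-in and is labelled as
such.

## The semi-simulated generator

`synth.make_dataset` emulates the semi-simulated validation construction:
`contaminated = pure + a·veog + b·heog` with known coefficient vectors and
event times.  Design of the pure-EEG model:

* **Sources.**  `n_channels − 5` cortical-like sources: band-limited noise
  with power spectral density ∝ 1/f² over 1–47 Hz (the spectral slope of
  resting scalp EEG; a flatter 1/f background is much rougher than real
  recordings and understates the lag-1 autocorrelation on which λ relies),
  multiplied by slow non-negative burst envelopes that make them
  super-Gaussian — the property the separation step requires.  Five sources
  are placed over the frontal region: frontal cortex is always active, and
  their moderate frontal weights give the outlier fence a realistic bulk.
* **Topographies.**  Smooth mono- or dipolar Gaussian profiles on a 2-D
  projection of the 10–20 layout.  Smooth profiles on 19 electrodes are
  near-collinear, so the mixing matrix is blended toward its orthogonal
  polar factor until its condition number is ≲12 — honouring the
  invertible-mixing precondition of the source model rather than violating
  it by construction.
* **Alpha.**  Two spindle-like 8–12 Hz oscillators with posterior
  topographies plus a small global far-field gain, so every channel shows
  an alpha bump.
* **Noise.**  10 % independent pink sensor noise per channel; channel
  amplitudes scaled to an 18 µV mean RMS.
* **Artifacts.**  Blinks are squared-cosine bumps, 200–400 ms wide,
  100–400 µV, ≥0.8 s apart, apices on the sample grid; saccades are
  smoothed step pulses with 0.5–1 s plateaus.  Propagation decays
  exponentially with 2-D distance from the eyes (`tau = 0.5` head radii):
  the blink profile is the summed proximity of both eyes (non-negative,
  prefrontal-dominant, peak coefficient 1.0 — chosen so the frontal
  artifact RMS lands at the few-tens-of-µV scale typical of semi-simulated
  validation data); the saccade profile is the signed left/right proximity
  difference (antisymmetric, zero on the midline), matching the opposite
  polarity of horizontal eye movements over the two hemispheres and keeping
  the two ocular topographies linearly well separated.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genuine volume-conduction forward physics (an
explicit non-goal), non-stationary drifts, electrode pops, muscle and
cardiac artifacts, line noise, and overlapping blink–saccade events.  Real
recordings also contain many more weak sources than channels, so real
decompositions are never as clean as the simulated ones; the benchmark
orderings should transfer, the absolute metric values should not be read as
predictions for real data.

## Problem sizes

The identification battery uses 20 datasets per condition (19 channels,
200 Hz, 120 s, 12 blinks/min); the method-comparison benchmark uses 20
datasets with the same geometry plus 2 saccades/min; the source-recovery
check uses 3 Laplacian sources at 20 000 samples.  These sizes give stable
medians while keeping a full run in the minutes range on one CPU.

## Known limitations

* The Tukey fence on frontal weights can flag a dominant posterior
  component on average-referenced data (its reference leakage is constant
  across channels), and conversely a weak blink in a low-artifact recording
  can stay under the fence; the confirmatory correlation gate at 0.5
  reduces but does not eliminate either error.
* λ as defined is unstable on weakly contaminated channels; the 0.02
  contrast guard excludes such channels from averages rather than repairing
  the definition.
* The wICA baseline approximates, not reproduces, the original threshold
  rule.
* With 19 channels the separation of more sources than channels is
  impossible in principle; ocular components separate cleanly because they
  dominate, but residual mixing among weak cortical sources is expected.
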