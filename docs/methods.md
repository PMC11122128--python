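# Methods

## Signal model

A cropped eye-image sequence J = {I₁ … I_k} (grayscale, m×n per frame) is
reduced to a k×d block-energy matrix E: frame i is tiled by a rows×cols
grid (default 6×8 → d = 48 blocks of 16×16 px on a 96×128 crop) and
E[i, b] is the sum of squared intensities over block b. 8-bit frames are
divided by 255 before squaring so energies are O(block area) regardless of
input dtype; float frames are assumed to already be on the intended scale.
Frames not divisible by the grid are cropped at the right/bottom edge
rather than padded — zero-padding would create permanently dark blocks
whose energies distort the spatial correlation structure.

The thin SVD E = U Σ Vᵀ factorizes the sequence into temporal modes
(columns of U) ordered by energy. u₁ captures the quasi-static scene;
u₂ … capture temporal change (blinks, pupil saccades, head-motion
transients). One of u₂…u₁₀ is selected as the 1D temporal eye-change
signal, min–max scaled to [0, 1] and smoothed by a centered 5-frame
(~167 ms) moving average with edge truncation. A constant vector carries
no temporal information and maps to 0.5 everywhere.

### Vector selection

Each candidate is preprocessed exactly like the final signal, mean-removed
and Fourier transformed; the default score is its total spectral power in
a predefined band, and the candidate with the highest score wins (ties go
to the lowest rank). Numerical choices that matter:

* **Band, default [2, 15] Hz at 30 FPS.** The band targets the transient
  range: blink events last ~300 ms and concentrate spectral energy at
  roughly 2–7 Hz, saccade onsets are broadband, whereas gaze-level drift,
  illumination change and the piecewise-constant component of fixation
  sequences live below ~2 Hz. Opening the band down to 0.5 Hz makes slow
  step-like components outscore blink-carrying vectors; both edges are
  exposed in the API.
* **Score, default band power; single-bin peak magnitude available.**
  After min–max scaling every candidate has unit dynamic range, so the
  score is a pure shape criterion. Total in-band power is markedly more
  stable than the largest single bin, which flips between competing
  vectors when two modes have comparable peak bins.
* **Candidate energy floor (σ_j ≥ 0.01 σ₁).** Shape-based scoring is
  blind to how much of the matrix energy a vector explains, so pure
  sensor-noise directions — flat, broadband spectra — would compete on
  equal terms. Vectors below 1% of σ₁ are excluded; if none qualify the
  pool falls back to all of u₂…u₁₀. Directions with σ_j ≤ 10⁻¹⁰ σ₁ are
  numerically null (LAPACK returns an arbitrary orthonormal complement)
  and are treated as information-free: a fully static sequence therefore
  yields an exactly flat signal at 0.5.
* Preprocessing happens *before* scoring (scale → smooth → FFT → select);
  the alternative order is a one-line change but the smoothing acts as the
  same low-pass filter on every candidate either way.

Singular-vector sign is not identifiable; v and −v produce signals
mirrored about ½ with identical non-DC spectra, so all downstream spectral
features are sign-invariant and tests compare signals up to that
reflection.

## Baselines

**EAR.** (‖p2−p6‖+‖p3−p5‖)/(2‖p1−p4‖) per frame from the 6-point contour;
missing frames (failed detection) are linearly interpolated, edge gaps
take the nearest observed value. The series is robust-scaled by the median
and raw MAD (no 1.4826 consistency factor — the statistic is a scale
reference, not a normal-σ estimate) of the session's first 20 s, assuming
attentiveness at session start; a zero calibration MAD falls back to the
full-session MAD, then to centering only. The EAR feature pipeline
consumes the scaled series mapped to [0, 1]; no moving average is applied
(smoothing belongs to the SVD path).

**Gaze.** From a horizontal iris track: a frame is a *saccade* if
|Δx| ≥ 1 px versus the previous frame, a *fixation* if Δx = 0, and
unlabeled for sub-threshold drift (possible with sub-pixel tracking; the
two rules are not exhaustive there). Percentages divide by the k−1
decidable frames so a constant track gives fixation = 1. Velocity pools
all saccade frames: Σ|Δx| over their count; a per-episode mean is exposed
as an option of interpretation but pooled is the default.

## Time-series features

15 statistical and 17 spectral feature families, pinned definitions
(one-sided FFT of the raw, unwindowed signal; psd = |X|²/n):

* Signal entropy: Shannon entropy (bits) of a 10-equal-width-bin
  histogram, normalized by log₂10; constant → 0.
* Maximum/median frequency: 95% / 50% quantiles of cumulative |X|.
* Power bandwidth: −3 dB width of the psd (0 for a one-bin spectrum).
* Spectral moments (centroid, spread, skewness, kurtosis) treat |X|,
  normalized to sum 1, as a distribution over frequency.
* Spectral decrease, distance (cumulative |X| minus the straight line to
  its total), slope (least-squares on |X| vs f), entropy (normalized,
  nats, on psd), variation (one minus the normalized correlation of the
  spectrum with its one-bin shift), fundamental frequency (lowest
  above-DC local maximum of |X|).
* Wavelet features: continuous wavelet transform by convolution with the
  sampled Ricker (Mexican-hat) kernel of length min(10a, n) at scales
  a = 1…9 (scales 5 and 8 always present). This is the classic discrete
  CWT scheme and is implemented explicitly so every coefficient is
  reproducible by a direct-formula oracle; per scale the RMS energy and
  variance are reported plus the Shannon entropy of relative scale
  energies. Degenerate spectra (all-zero) yield 0 for ratio-based
  features rather than NaN.

## Feature selection and evaluation

Selection fits one joint OLS of the 0/1 label on all features (a linear
probability model, deliberately not logistic); two-sided t-test p-values
at n−q degrees of freedom; keep p ≤ 0.05, no multiple-testing correction
— the raw threshold is the procedure being reproduced. Collinear columns
are dropped greedily left-to-right with a warning; a univariate fallback
exists for n < q tables.

Evaluation: stratified 5-fold CV; random undersampling of the majority
class in training folds only (test folds keep the natural imbalance, and a
checksum over the test rows asserts they are never touched). Per-class
"accuracy" is that class's recall; per-class F1 treats the class as
positive; AUROC is threshold-free on predicted probabilities; the ±
values are across-fold SDs. XGBoost: 1000 rounds, AUC metric on a 20%
stratified slice of the training fold, no early stopping, single-threaded
for bit-reproducibility. MLP: one hidden layer of 12 ReLU units, sigmoid
output, log-loss (binary cross-entropy), Adam, batch 16, 100 epochs,
standardized inputs, seeded initialization; epochs/batch are free
parameters the underlying study does not pin down.

## Synthetic data generator

The generator emulates the labeled 20-s, 30-FPS eye-crop windows of a
probe-caught webcam study: a light sclera ellipse (aperture = vertical
axis) on darker skin, a dark pupil disc clipped by the eyelid, i.i.d.
Gaussian pixel noise (σ = 2 on the 8-bit scale), 8-bit quantization.
Blinks are symmetric linear close–open ramps (9 frames ≈ 300 ms). Three
regimes encode the behavioral contrast of interest:

* **Focus** — stationary boundary, active horizontal pupil saccades:
  60/min, ±8 px jumps (a few percent of the eye width, the scale of
  on-screen reading saccades at this crop resolution), ~8-frame dwells.
* **nonFocus_fixation** — long fixation: pupil constant outside blinks.
* **nonFocus_headmotion** — added slow sinusoidal whole-frame translation
  (6 px) and rotation (5°).

All regimes share blink_rate = 12/min (4 blinks per window): blink rate is
deliberately *not* a class cue, so any discrimination must come from pupil
and head-motion information — precisely what the SVD signal is claimed to
carry and EAR to lack. The published literature does not quantify
per-state blink/saccade rates; these defaults are design choices of the
generator, not claims about human behavior. Landmarks for the EAR pipeline
are emitted analytically from the eyelid ellipse (optional Gaussian jitter
emulates detector noise, default off).

What the generator does **not** model: photometric texture (iris gradients,
eyelashes, specular highlights), vertical saccades, compression artifacts,
illumination drift, partial blinks. Consequently blink and saccade events
separate into cleaner singular components than in real video, and passing
tests demonstrate the pipeline's mechanics and its claimed qualitative
contrasts — not field performance on human recordings.

## Problem sizes

The packaged experiments run at desk scale by design: 600-frame sequences,
120-sequence datasets at 5:1 imbalance for the cross-validated comparison,
1000 replicates at n = 200 for the selection-calibration check, and
k, d ≤ 12 matrices for the exact-oracle comparisons.

## Known limitations

* Vector selection remains a shape contest between the blink-carrying and
  saccade-carrying components; on a minority of random draws the saccade
  vector wins and blinks then appear only as secondary deflections of the
  selected signal.
* The feature definitions are pinned but not unique readings of their
  one-line descriptions (entropy binning, bandwidth, spectral distance
  have defensible alternatives); all are documented above and fixed in
  code.
* Left eye only by default; averaging both eyes is exposed but untested
  against any ground truth.
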