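# Methods

## The problem and the design

The pipeline classifies routine 60 s multichannel EEG recordings as
epileptic or non-epileptic. Its purpose is a *controlled* comparison of two
classifiers: a single feature table is computed once and fed to both
tracks, so any performance difference is attributable to the classifier,
not the features. Because clinical corpora of this kind are generally not
shareable, the package includes a first-class synthetic-data module that
emulates the corpus the analysis assumes; every result the package reports
is computed on that synthetic corpus.

## Synthetic corpus

**What it emulates.** 21 subjects (15 epileptic, 6 healthy), 5 recordings
each: 105 recordings of 60 s, band-limited 0–80 Hz. Channel count is
configurable (default 16 for desk-scale work; 256-lead montages are
supported and produce the same feature-vector length because features are
averaged across channels). Sampling rate defaults to 250 Hz, a common
clinical rate whose Nyquist frequency comfortably covers the 0–80 Hz band.

**Background.** Colored noise shaped by the canonical rhythm bands — band-
passed Gaussian noise at unit RMS per band, scaled by the square root of
the band weight (weights are relative powers; defaults δ 1.0, θ 0.7,
α 1.0, β 0.5) plus a low-level broadband component up to 80 Hz
(`noise_level` 0.2). Channels mix a shared per-band source (60%) with
per-channel noise (40%), giving the cross-channel correlation scalp
recordings show. Each subject's band weights are jittered log-normally
(σ = 0.15) so subjects differ in rhythm composition. Overall RMS is scaled
to 20 µV.

**Epileptic activity.** Interictal spike-and-slow-wave transients: a
biphasic sharp spike (default width 70 ms, a typical epileptiform spike
duration) followed by a slow half-wave of 4× the spike width at 0.45
relative amplitude. Events occur at Poisson-distributed times (default
20/min), each on a random contiguous span of ¼–½ of the channels (focal
character), with amplitude `spike_amplitude_factor` (default 8) times the
channel's background RMS. Ground-truth onsets and channel spans are kept
as an event log and written as a TSV sidecar.

**What it does not emulate** — and hence what passing tests do not show
about clinical data: eye-blink/EMG artifacts, electrode drift, ictal
dynamics, volume-conduction head geometry, and inter-subject variability
beyond rhythm-weight jitter. At the default amplitude factor the classes
are separable almost perfectly; the generator is a correctness and
protocol-fidelity instrument, not a difficulty benchmark. Lower factors
(1–2) produce overlapping classes for stress-testing.

## Preprocessing

The recording band (0–80 Hz) is enforced with an 80 Hz low-pass FIR
(Hamming window, 251 taps at fs = 250), applied forward–backward so the
effective filter is zero-phase and the stopband attenuation is doubled.
An optional 0.5 Hz high-pass is available. Artifact removal by ICA is a
manual, operator-dependent step on real data and is deliberately outside
the pipeline; externally cleaned recordings can enter through the EDF or
internal-container readers.

## Empirical mode decomposition

Classical envelope sifting: natural cubic splines through the strict local
maxima/minima (plateaus contribute their midpoint once), with the two
extrema nearest each record end reflected across the boundary to tame
spline end swings. The working signal is repeatedly reduced by the mean of
the upper and lower envelopes.

**Stopping.** A candidate is accepted at the first iteration where the
Cauchy ratio SD = Σ(h_prev − h)² / Σh_prev² falls below 0.2 *and* the mode
condition |#extrema − #zero-crossings| ≤ 1 holds. The SD criterion alone
stops after a handful of passes on broadband signals but leaves dozens of
riding waves (extrema without zero crossings); requiring the mode
condition makes every returned IMF a genuine mode. On 60 s broadband
channels the joint stop typically needs 30–130 passes for IMF 1, so the
iteration cap is a generous 300. Three IMFs are extracted (configurable);
decomposition stops early if the residual becomes monotone. The residual
is retained, which makes reconstruction (ΣIMF + residual = input) exact to
floating-point round-off by construction — verified at 1e−8 relative in
tests.

The sifting loop runs in a compiled (numba) kernel; the same envelope
construction is also exposed through `find_extrema`/`compute_envelopes`
built on `scipy.interpolate.CubicSpline`, and the two routes are asserted
to agree to 1e−10 in the test suite. An independently coded reference
decomposition (dense-solve splines, `argrelextrema`, its own loop) lives
in the test suite as a cross-check oracle; correlations of the first three
IMFs across the two routes exceed 0.9 on tone-and-noise fixtures.

## Features

16 values per recording (channel-averaged; a concatenation mode keeps
per-channel columns):

| family | values | notes |
|---|---|---|
| Welch PSD | total 0.5–80 Hz power; δ, θ, α, β, 30–80 Hz band powers | 2 s Hann windows, 50% overlap; density scaling so ∫PSD df ≈ variance (checked within 5%) |
| Shannon entropy | 1 | amplitude histogram, 64 equal-width bins over [min, max]; −Σp log₂ p with 0·log 0 = 0; constant signal → 0 bits |
| IMF moments | mean, skewness, kurtosis × 3 IMFs | population (1/N) estimators; kurtosis non-excess (Gaussian → 3, lower bound 1) |

Channel averaging was chosen because it makes the vector length
independent of the montage, allowing the 256-channel configuration without
a 256× dimensionality blow-up; whether a clinical analysis would
concatenate instead is unknowable, so both modes exist and aggregation is
the default. Entropy is computed on the amplitude distribution (the
minimal reading of an event-probability entropy for a time series);
spectral entropy is deliberately not substituted.

## Classifier tracks

- **SVM track.** 7:3 stratified recording-level split. Z-score scaling fit
  on training rows only. RBF-kernel SVC; exhaustive 81-pair grid
  C, γ ∈ {2⁻⁴…2⁴}; each pair scored by mean 5-fold stratified CV accuracy
  on the training rows; ties break toward smaller C then smaller γ (the
  smoothest model); winner refit on all training rows. Decision scores are
  the SVM margin.
- **GBDT track.** 8:2 stratified split. Welch two-sample t-test per
  feature between classes on training rows; keep p < 0.05, falling back to
  the single smallest-p feature so the model never loses all inputs; then
  scaling. Gradient boosting (deviance loss) with learning rate 0.1 and a
  small 5-fold-CV-selected grid: trees ∈ {50, 100, 200}, depth ∈ {2, 3} —
  canonical values for the algorithm; the corpus is far too small to
  support a wider search. Scores are positive-class probabilities.

Splits are recording-level by default, so recordings of one subject can
span train and test — with 5 recordings per subject this leaks subject
identity and inflates test metrics; this mirrors the plain "random
stratified sampling" protocol. A subject-level split
(`SplitSpec(unit="subject")`) stratifies whole subjects instead and is
flagged in the results file; it is the stricter protocol for clinical
claims.

CV model selection uses accuracy, matching the headline metric. All
randomness (splits, fold shuffling, tree seeds) derives from one global
seed by fixed offsets, so stages can be re-run in isolation and the whole
experiment is byte-reproducible.

## Evaluation

Positive class = epileptic. Sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy, precision TP/(TP+FP), F1 = 2·P·R/(P+R), reported as
percentages; zero-denominator cells become NaN ("undefined") rather than
raising. (Some texts print the sensitivity/specificity pair with TP and TN
interchanged; this package uses the standard orientation throughout, which
is the only one consistent with a TP-based precision.) ROC is swept over
all unique score thresholds and AUC integrated by the trapezoid rule,
which equals the tie-averaged Mann–Whitney statistic — asserted to 1e−12
against a pair-counting oracle.

Two evaluation modes are reported and labelled: `test_set` (the track's
own held-out split; the default report) and `cv_pooled` (scores pooled
from an outer 5-fold CV in which the full track protocol, selection and
scaling included, is refit per fold; enabled with `report_cv_pooled`). The permutation-sanity check (label-shuffled AUC ≈ 0.5) uses
the pooled mode: a 32-row test split gives the null AUC a standard
deviation of ≈ 0.115, wider than any reasonable "chance band", whereas
pooling all 105 recordings tightens it to ≈ 0.063.

## Numerical choices and degenerate inputs

- Sift envelopes need ≥ 2 maxima and ≥ 2 minima; fewer signals a monotone
  residual and stops decomposition cleanly.
- Zero-variance signals make skewness/kurtosis undefined → a
  degenerate-input error naming the channel and IMF.
- Zero-variance features scale to 1 (becoming constant 0) with a warning.
- EDF export quantizes to 16 bits against a symmetric per-channel physical
  range (error ≤ range/2¹⁶); the internal container stores float32.
- Grid-search and CV tie-breaks are first-in-order (smaller C/γ, smaller
  ensemble), making selection deterministic.

## Problem sizes used in the checks

The test suite runs the full experiment at the default corpus scale
(105 recordings × 16 channels × 60 s) for five generator seeds, plus a
twice-repeated run for bit-level determinism; unit tests use a reduced
corpus (21 recordings, 2–4 channels, 10–15 s). The acceptance script runs
one full-scale experiment. These sizes were chosen so a complete
verification pass stays comfortably on one CPU core.

## Known limitations

- Synthetic separability at the default spike amplitude is near-total;
  reported 100% accuracies characterise the pipeline's correctness, not
  expected clinical performance.
- EMD is the classical univariate algorithm; no ensemble (EEMD) or
  multivariate variants, and no Hilbert spectral features.
- The EDF writer is minimal (one record per second, integer sampling
  rates, zero-padded final record) — sufficient for round-tripping this
  pipeline's recordings, not a general-purpose EDF library.
- Recording-level splits leak subject identity (above); subject-level
  evaluation is the stricter protocol for clinical claims.
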