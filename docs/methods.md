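# Methods

This note documents the models, algorithmic choices, parameters, and
limitations of `cryclass`, in the order the pipeline runs.

## Preprocessing

A clip is peak-normalized (max |sample| = 1; an all-zero clip is an
error), cry units are detected on the un-preemphasized signal, and each
unit is then pre-emphasized (`y[n] = x[n] − 0.97·x[n−1]`), framed, Hamming
windowed, and FFT-transformed. Detection precedes pre-emphasis because
short-time-energy thresholds are more stable before high-pass filtering.

**Cry-unit detection** is a classic double-threshold algorithm: 20 ms
analysis windows with 10 ms hop; windows whose energy reaches 10% of the
clip's maximum window energy seed a unit, which is expanded outward while
energy stays above 2% of the maximum and the zero-crossing rate stays at
or below 0.5 (the ZCR guard rejects noise tails). Units closer than
50 ms are merged; units shorter than 100 ms are dropped. Each active
window contributes its hop span to the detected interval; using the full
window span instead over-extends unit tails into silence by the
window–hop difference (measured on the generator: 99.5% of true voiced
time recovered with 3.8% silence inclusion at these defaults).

**Framing** uses 1024-sample frames with 50% overlap (≈23 ms at
44.1 kHz, 64 ms at the 16 kHz test scale); the trailing partial frame is
dropped rather than zero-padded to avoid padding bias in frame
statistics. Stereo input is averaged to mono. All parameters are
configurable through `FeatureConfig`.

## Features

Twelve per-frame features; exact definitions:

- **Magnitude** `Σ|S(i)|`, **average** (signed mean), **variance**
  (population, divisor N), **zero-crossing rate** (fraction of adjacent
  pairs with differing sign; a zero sample inherits the previous sign,
  and a leading zero counts against the first nonzero sample).
- **Bandwidth**: power-weighted spectral spread about the power-weighted
  centroid, in bin² (no square root).
- **Peak / valley**: per subband, the natural log of the mean of the
  top/bottom ⌈α·N_k⌉ magnitudes after sorting descending; α = 0.2;
  four subbands with edges at Nyquist fractions {0, 1/32, 1/8, 1/2, 1}
  (a logarithmic partition); logs floored at ln 1e−10.
- **Pitch**: normalized autocorrelation peak over lags corresponding to
  250–600 Hz, with parabolic interpolation of the peak (sub-sample lag
  resolution; without it the lag quantization alone costs up to ~1.5%
  error at the top of the band at 16 kHz). Frames whose peak falls below
  the voicing threshold 0.3 are unvoiced (pitch 0). Pitch uses a
  dedicated 4096-sample window centered on the analysis frame and clamped
  to the cry unit, on the un-preemphasized signal — a 1024-sample frame
  holds too few periods at 250 Hz, and pre-emphasis attenuates the
  fundamental.
- **Formants F1–F6**: LPC by the autocorrelation (Levinson–Durbin)
  method, order 18; roots with positive imaginary part, 3 dB bandwidth
  −(fs/π)·ln|z| under 700 Hz, and frequency in (90 Hz, Nyquist − 50 Hz)
  are kept, sorted ascending, zero-padded to six.
- **LPCC (12)**: the standard cepstral recursion
  `c_m = a_m + Σ_{k<m} (k/m) c_k a_{m−k}` applied to the LPC prediction
  coefficients.
- **MFCC (12)**: triangular HTK-mel filterbank (26 filters, 0 Hz to
  Nyquist) on the magnitude-squared spectrum, log energies floored at
  1e−10, orthonormal DCT-II, coefficients 1–12 (coefficient 0, the
  overall level, excluded). **ΔMFCC**: regression delta with window 2,
  edges replicated; computed per cry unit so deltas never span a unit
  boundary.

**Clip aggregation**: mean and standard deviation of each dimension over
cry-unit frames (112 columns). Pitch statistics use voiced frames only —
averaging in unvoiced zeros would drag a clip's pitch mean below its true
F0 band. Frame-level rows are also available (`unit="frame"`), with
clip-level prediction by margin-weighted plurality over frames.

## Variable selection

A two-step forest procedure at the feature-family level (the twelve
families: magnitude, average, variance, zcr, bandwidth, peak, valley,
pitch, formant, lpcc, mfcc, dmfcc; per-dimension mode available):

1. **Importance and threshold.** Importance is Breiman's out-of-bag
   permutation importance: for each tree, the drop in that tree's own
   OOB accuracy when the family's columns are jointly permuted, averaged
   over trees and repeats (5 by default). The per-tree form is essential
   here: ensemble-majority OOB accuracy saturates at 1.0 on separable
   data, where permuting any one of several redundant informative
   families shows zero effect; individual trees are imperfect, so their
   accuracy still drops. The elimination threshold is the largest
   importance observed in decoy runs with permuted labels (3 runs) — a
   shadow-feature rule in the spirit of Boruta. On the null simulations
   importances stay below ~0.04 while informative ones reach 0.1–0.3, so
   the two regimes are well separated; with all-noise inputs nothing
   survives and the selected set is empty.
2. **Interpretation.** Nested forests on the top-1, top-2, … surviving
   families; the smallest subset whose OOB error (majority vote over each
   sample's OOB trees) is within one binomial standard deviation of the
   minimum is kept.

Forests default to 2000 trees (the selection-quality setting); the test
suite and acceptance simulations use 300–500 trees, which reproduce the
same selections at a fraction of the cost.

## Grouped-support-vector network

A committee of `n_members` (default 300; 50 at test scale) RBF-kernel
SVCs (one-vs-one multiclass), built by SAMME-style boosting:

- Sample weights start uniform. Each round draws a weight-proportional
  bootstrap resample, splits it 80:20 stratified, fits the SVM on the
  80%, and computes the validation error ε weighted by the current
  weights of the validation rows.
- Vote weight = `ln((1−ε)/ε) + ln(K−1)`, floored at 0 and capped at
  ln 1e6 (ε = 0); members at or worse than chance (ε ≥ (K−1)/K) get
  weight 0 and reset the weights to uniform. Misclassified training rows
  are multiplied by `exp(vote_weight)` and weights renormalized.
- Prediction: per row, each member adds its vote weight to its predicted
  class; scores are normalized to sum 1 (usable as ROC scores); ties go
  to the earlier class in the model's class order. If every member ends
  with zero weight (possible only on degenerate inputs), votes fall back
  to validation accuracies so the committee stays usable.
- A plain-bagging mode (uniform resampling, vote weight = validation
  accuracy) is provided for ablation.

One `(C, γ)` is grid-searched once over C ∈ {1, 3, 33} and
γ ∈ {0.1, …, 5.0} (step 0.1) by stratified CV and shared by all members;
ties break toward smaller C, then smaller γ. Features are z-scored with
each member's fit-split statistics — RBF kernels are scale-sensitive.
Note the γ grid presumes a low-dimensional input (post-selection); on the
full 112-column clip matrix even γ = 0.1 drives the kernel toward zero.

## Evaluation

Mean accuracy is the **unweighted mean of per-class (row-wise)
accuracies**, not pooled accuracy — with the 12-feature count table the
row-wise mean gives 0.9120 while pooled gives 0.9162, and the former
matches the published convention. Displayed accuracies are truncated
(not rounded) to four decimals (113/129 = 0.87596 → 0.8759); full
precision is kept internally. Cross-validation is stratified k-fold
(default 10) over the whole committee, each row validated exactly once,
out-of-fold predictions pooled into one confusion matrix; ROC/AUC is
one-vs-rest on the normalized vote scores.

By default, feature selection runs once on the full dataset *before*
cross-validation, mirroring the select-then-evaluate protocol this
pipeline reproduces; this leaks selection information across folds.
`selection_in_fold` (or simply running selection on a held-out portion)
gives the unbiased variant.

## Synthetic data

The generator emulates the acoustic structure that the pipeline's stages
depend on, not infant physiology: a glottal-like impulse train at a
class-conditional F0 (drawn per burst, with 2% vibrato at 5 Hz), cascaded
two-pole resonators (bandwidth 150 Hz) at class formant centers jittered
±5% per clip (inter-infant vocal-tract variation), 600–900 ms bursts
separated by 200–350 ms pauses (inspiration), 10 ms cosine ramps, white
noise at 25 dB SNR, alternating sex tags. Defaults are 2 s clips at
16 kHz — enough for 2–3 cry units per clip — with full-rate, full-length
generation available; these sizes keep the suite and the acceptance run
to minutes on one CPU.

Presets: `separable` (disjoint F0 bands — sleep 260–330, hunger 400–480,
discomfort 500–590 Hz — and well-spaced formants) and `overlapping`
(identical F0 bands, formant centers differing by ~1%, far less than the
±5% within-class jitter). The two form a difficulty knob: cross-validated
accuracy is ≈1.0 on the former and falls toward the 1/3 chance level on
the latter.

What passing tests on this generator do **not** show: robustness to real
recording conditions (reverberation, handling noise, other voices),
pathological cries, inter-infant variability beyond formant jitter, or
any claim that the class-conditional acoustics match real hunger / sleep
/ discomfort cries — no public statistics exist for those distributions,
so class acoustics here are fictional and explicitly parameterized.

## Numerical choices and degenerate inputs

- Logs floored at 1e−10 (peak/valley, MFCC energies).
- All-zero spectra: bandwidth defined as 0 with a warning; zero-energy
  frames: formants and LPCC return zero vectors with a warning.
- Autocorrelation via FFT (exact to rounding; verified against direct
  summation); LPC via Levinson–Durbin (verified against a direct
  Toeplitz solve).
- ε = 0 members capped at vote weight ln 1e6; exact vote ties broken by
  class order; empty bootstrap classes redrawn (up to 20 times, then
  uniform).
- All randomness flows through `numpy.random.default_rng` seeds; fixed
  seed + fixed input reproduce models, predictions, and report files
  byte-for-byte.

## Known limitations

- End-point and cry-unit detection are implemented as a single combined
  detector; expiratory-phase segmentation finer than the energy envelope
  is out of scope.
- No denoising beyond silence trimming; heavy background noise will
  degrade both detection and features.
- The boosting scheme treats the committee's base learner as fixed
  (shared C, γ); per-member hyperparameters were judged not worth the
  300× grid cost.
- Selection before CV (the default, for protocol fidelity) optimistically
  biases cross-validated accuracy when selection is data-driven.
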