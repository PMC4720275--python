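# Methods

`tonocortex` implements a bedside EEG probe of auditory-cortex function in
two stages: (1) automatic detection of the N100 auditory evoked potential
with a wavelet/t-statistic procedure ("t-CWT"), and (2) detection of
frequency-selective cortical processing by decoding the stimulus frequency
from single-trial scalp EEG with linear support-vector machines.  Both
stages are driven by a passive tone-burst protocol and are testable end to
end against a built-in synthetic ERP generator.

## Stimulus protocol

Tone bursts of 200 ms come in 12 types: four carrier frequencies
(250, 500, 1000, 2000 Hz) crossed with three stimulation modalities (left
ear, right ear, binaural).  A default session presents 200 bursts of each
type (2400 total) in pseudo-random order with two constraints: exact
per-type counts, and no immediate repetition of the same type.  The
scheduler shuffles the full type multiset and repairs adjacent repeats by
swapping each offender with the nearest position where both ends of the
swap stay legal; this guarantees the counts by construction and terminates
for every non-degenerate multiset.  The inter-stimulus interval is drawn
i.i.d. uniform from [600, 800] ms and is interpreted by default as the
silence *after* the burst (offset-to-onset), the common ERP convention; an
`isi_mode="onset"` switch makes it onset-to-onset instead.  Session breaks
are not modeled — they do not affect epoch-level analysis.

## Preprocessing

Continuous recordings (1000 Hz, 10/10 montage; 64 recorded channels of
which 63 are analyzed) are processed in this order: epoch extraction,
power-line band elimination, artifact screening, bad-channel
interpolation, 30 Hz low-pass, baseline correction.

- **Epochs** span the half-open window [-50, 350) ms around each onset
  (400 samples; t = 0 is the first poststimulus sample).  Events whose
  window leaves the recording are dropped with a warning.
- **Filters** are order-2 Butterworth: a 45–55 Hz band-stop (the text of
  the acquisition protocol says "band-pass ... eliminated the interval
  45–55 Hz", which describes a band-stop) and a 30 Hz low-pass.  Both are
  applied forward-backward, so they are zero-phase — a symmetric peak's
  latency is unchanged — at the cost of doubling the effective order.
- **Artifact screening** flags any (trial, channel) whose absolute voltage
  exceeds 100 µV.  A channel flagged in more than 20% of trials is
  globally bad and interpolated; any remaining flag on a good channel
  rejects the trial.  This two-stage rule reproduces both behaviors the
  acquisition description implies (rejection and interpolation) with
  configurable thresholds.  A user-supplied trial-exclusion list covers
  manually identified ocular artifacts.
- **Interpolation** is a Perrin-style spherical spline (order m = 4,
  30 Legendre terms, ridge 1e-8) on idealized unit-sphere 10/10
  coordinates generated from the electrode-naming grid (18° per 10% step).
  The spline reproduces constants exactly through its bias term and
  degree-1 fields to well under 5% of range.
- **Baseline**: the mean over [-50, 0) ms is subtracted per trial and
  channel.

## N100 detection (t-CWT)

Every trial at Cz is decomposed with the L2-normalized Mexican-hat wavelet
ψ(u) = 2/(√3·π^¼)·(1-u²)·exp(-u²/2) on 120 scales linearly spaced from
8.33 to 250 ms:

c(b, s) = s^(-1/2) · Σ_t x(t)·ψ((t-b)/s)·Δt,

with zero padding at the epoch edges.  Across trials, each (scale, time)
point yields a one-sample Student t statistic; the N100 candidate is the
most negative t over all scales in the 80–150 ms poststimulus window.

Two numerical facts shape the implementation:

1. **Edge exclusion.** The largest scales' kernel support (±5s up to
   ±1250 ms) vastly exceeds the 400 ms epoch.  Zero padding then deflates
   the noise variance of those coefficients, which systematically pulls
   the t-minimum toward large truncated scales and away from the true
   component latency.  The detector therefore only searches (time, scale)
   points whose full support [b-5s, b+5s] lies inside the epoch; with the
   400 ms epoch this leaves scales up to ≈26–40 ms available throughout
   the window, which brackets the N100's temporal extent.  The standalone
   minimum-search operation searches every point unless asked otherwise.
2. **Degenerate scale covariance.** The per-trial coefficient vector
   across a wide scale grid at one time is numerically rank-deficient
   (condition numbers 1e13–1e18 at any decimation), because large-scale
   kernels restricted to a finite epoch collapse onto a low-order family.
   The Hotelling T² at the detected time is computed on every 4th scale
   (p = 30; coarsened once more when n ≤ 3p); if the sample covariance is
   still singular, T² is evaluated in the leading eigen-subspace
   (eigenvalues above 1e-9 of the maximum) with an F(r, n-r) reference,
   r being the numerical rank — the exact Hotelling test in the subspace
   the data actually occupy.

**Significance.** Testing at a data-selected minimum makes the plain F
reference anti-conservative: simulations of the full chain on pure pink
noise reject at 12–15% instead of 5%.  The reported p-value therefore
comes from a sign-flip randomization of the *entire* chain: each of 200
draws flips the sign of every trial independently, recomputes the
t-field (cheap, since sums of squares are flip-invariant), relocates the
minimum and recomputes T² there; extremeness is compared on the
parametric-p scale so draws with different effective ranks are
commensurable, and p = (1 + #extreme)/(n_flips + 1).  Under a
sign-symmetric null this test is exactly calibrated (measured 5.2% over
500 null datasets).  A detection is declared at the one-sided 5% level
when the randomization p is below 0.05 *and* the located minimum is a
negativity (t < 0).  The parametric F p-value is reported alongside for
reference.

## Frequency decoding

For each trial, the feature vector is the raw [0, 350) ms poststimulus
signal of all analysis channels, flattened channel-major (63 × 350 =
22050 features in the full montage; no scaling — an optional
standardization flag exists).  Four tasks are run per subject: stimulus
modality (3 classes, all trials) and stimulus frequency (4 classes)
within each modality.

Classification is one-vs-one: a linear SVM (SMO-family solver, C = 1,
gradient tolerance 1e-3) per class pair, majority vote over the pairwise
predictions, ties resolved toward the lowest class index.  Accuracy is
estimated by repeated random equal-size 4-fold cross-validation: per
repetition the trials are permuted, n mod 4 are dropped at random, each
quarter serves once as test set, and the repetition accuracy is the mean
of the four fold accuracies; the global accuracy averages 1000
repetitions (50 in the fast profile).  Per-class accuracy is class recall
pooled over the four folds and averaged over repetitions.

Significance uses a label-permutation test: each permutation shuffles the
labels and recomputes the CV accuracy with a single repetition (an
unbiased draw from the same statistic family at 1/1000th the cost);
p = #{null ≥ observed}/n_permutations, which can be exactly 0 — matching
the convention of reporting "0" for effects stronger than every
permutation — and the (k+1)/(n+1) variant is reported alongside.
Decoding outcomes are flagged at the 1% level in the cohort table.
Chance level is 1/K (25% for frequency, 1/3 for modality).

A caveat the tests acknowledge explicitly: with *small* samples,
random-split CV on null data sits slightly **below** chance, because a
test fold that over-represents a class under-represents it in training
and the classifier learns to disfavor it.  The bias shrinks with n and is
negligible at the calibration scale used here (320 trials, high-
dimensional features: measured 24.97% against the 25% chance level).

## Synthetic data generator

The generator states a world and keeps it fixed:

- **Waveform**: a Gaussian bump (peak -8 µV at the fronto-central pole,
  latency 100 ms, SD 15 ms) — deliberately *not* a Mexican hat, so the
  detector's wavelet is not trivially matched to the injected signal.
- **Topography**: spatial Gaussian kernels on the idealized montage — a
  negative pole midway between Cz and FCz and positive kernels at T7/T8
  (weight -0.55 each), normalized to +1 at the fronto-central maximum so
  the amplitude parameter reads in µV at the vertex.
- **Noise**: independent per-channel pink (1/f) noise, synthesized
  spectrally and rescaled to an exact sample SD (default 5 µV); an
  optional distance-decaying spatial mixing kernel is off by default.
- **Condition effects**: frequency conditions k = 0..3 are displaced
  symmetrically around the base template — latency ±5 ms, gain ±12.5%,
  and a lateral tilt of the negative pole, all multiplied by a single
  `effect_scale`; monaural modalities add a contralateral tilt, also
  scaled by `effect_scale`, so `effect_scale = 0` makes all 12 templates
  exactly identical (the null world used for calibration).  A
  per-modality multiplier (`modality_effect_scales`) can silence the
  frequency information of one pathway, emulating a unilaterally damaged
  auditory cortex.

The defaults were chosen once as plausible auditory-ERP magnitudes; no
effect-size estimates exist for the between-frequency differences in real
recordings, so green tests establish *internal* consistency (calibration,
recovery, monotonicity) — not that the generator matches human data.  The
generator also omits real-data features: correlated and non-stationary
noise, ocular/muscle artifacts beyond amplitude outliers, inter-trial
latency jitter, and any biophysical forward model.

## Profiles and budgets

The full acquisition-protocol sizes (63 channels, 200 trials/type, 1000
CV repetitions, 1000 permutations) cost hours of CPU; a `test` profile
(16 channels, 80 trials/class, 50 repetitions, 200 permutations) runs the
identical code paths in minutes and is used by the test suite and the
acceptance script.  All analyses are deterministic given the configured
seeds; reports regenerate byte-identically.

## Known limitations

- The EDF and BrainVision readers are minimal (uniform sampling rate,
  binary multiplexed data) and exist because no reader library is
  available in the target environment; they are not general-purpose.
- The electrode geometry is an idealized naming-grid sphere, not a
  digitized head; interpolation and topography tests hold on this
  geometry.
- The randomization p-value of the detector assumes sign-symmetric noise
  about zero; strongly asymmetric artifacts would distort it (the
  amplitude screening upstream limits this in practice).
- Per-frequency significance derives from per-class recall permutation
  nulls; an alternative reading (separate binary problems) would give
  different per-frequency p-values.
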