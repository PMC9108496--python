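# Methods

This note documents the models, estimators, and design choices behind
`emofc`, and what the synthetic studies do and do not demonstrate.

## The analysis being modeled

The pipeline reimplements a two-state music-evoked EEG emotion-recognition
analysis. Subjects listen to short music clips inducing high
valence-arousal (HVA) or low valence-arousal (LVA) emotion while 32-channel
EEG is recorded at 500 Hz on a 10–20 montage (M1/M2 mastoids as references,
30 scalp channels analyzed). Each subject receives 12 trials (6 per state),
each a 5 s rest / 20 s stimulation / 5 s rest sequence. The analysis has
four arms:

1. **Image classification.** After preprocessing, each stimulation second is
   decimated to 20 evenly spaced points per channel and the channels × 20
   matrix is min-max scaled onto [0, 255]; a depthwise-separable CNN with a
   softmax head classifies the two states under fivefold cross-validation.
   With the full protocol this yields 1800 per-second samples per class,
   split 1080 train / 360 validation / 360 test per class per fold.
2. **Channel-subset optimization.** Starting from the eight frontal channels
   (Fp1, Fpz, Fp2, F7, F3, Fz, F4, F8), sequential backward selection
   evaluates every leave-one-out subset per level with a cross-validated
   classifier and greedily removes the channel whose removal scores highest,
   down to two channels (33 evaluations from 8 to 2).
3. **Functional connectivity.** Per trial, the magnitude coherence

       Coh_xy(f) = |mean_k X_k(f) conj(Y_k(f))| /
                   sqrt(mean_k |X_k(f)|^2 · mean_k |Y_k(f)|^2)

   over Hann-tapered segments k, band-averaged over 1–40 Hz, fills a
   channels × channels FC matrix. Per-subject mean FC (Fisher z of the
   upper-triangle entries, averaged, back-transformed for display) is
   compared between states with a paired t-test.
4. **Dynamic FC classification.** The first k = 1…6 trials' FC matrices of
   each subject/state are concatenated side by side into an n_ch × (n_ch·k)
   image and classified; accuracy as a function of k is the dynamic-FC
   curve.

## Synthetic data: the generative model

Real recordings for this protocol are not publicly deposited, so the
package ships a generator that emulates the protocol and plants the
statistical structure the analysis assumes. All signals are synthesized in
the frequency domain: each window is the inverse FFT of independent
complex-Gaussian spectra with prescribed one-sided PSDs, making planted
band powers and coherences exact population quantities.

* **Background**: per-channel 1/f Gaussian noise (exponent 1.0, total RMS
  10 µV), plus band-limited oscillations on every channel (alpha 8–13 Hz at
  relative power 1.0 and beta 18–25 Hz at 0.5; 25 µV² total at unit
  multiplier). Rest windows contain background noise only.
* **Amplitude contrast**: during stimulation, oscillation power on the
  discriminative channels (default: the eight frontal channels) is
  multiplied by (1 + `amplitude_effect`) under the boosted state (default
  HVA, effect 1.0 → doubled power). This is a *variance* contrast: the
  class means are identical.
* **Coherence plant**: each coherent pair (a, b) shares a unit-PSD source s
  confined to 1–40 Hz, mixed as a = n_a + w_a s, b = n_b + w_b s. With
  u = c/(1−c) and w_i(f)² = u·N_i(f) (N_i the channel's background PSD),
  the pair's population magnitude coherence is exactly c at every in-band
  frequency, for any asymmetry between the channels. When pairs share an
  endpoint the weight equations couple; a fixed-point iteration (a
  contraction for c < 1) solves them so every pair still hits its target.
  Defaults plant the three prefrontal pairs (Fp1–Fp2, Fp1–Fpz, Fpz–Fp2) at
  0.25 under HVA and 0.35 under LVA, so the low-arousal state carries the
  stronger prefrontal coupling — the direction the FC comparison is
  designed to detect.
* **Ocular artifact (optional, off by default)**: a shared 0.3–3 Hz source
  projected onto frontal channels (weight 1.0 prefrontal, 0.4 F-row),
  enabling exercise of the regression-based artifact-removal stage. Enabling
  it perturbs the planted prefrontal coherences, as a real artifact would.

What the generator does **not** model: inter-subject variability beyond
independent noise realizations, non-stationarity within trials, volume
conduction, real electrode noise, or any acoustic property of the music.
Passing tests therefore demonstrate the *pipeline's* correctness and the
internal consistency of its estimators on data satisfying its assumptions —
not performance on real EEG.

## Preprocessing

Notch (49–51 Hz band-stop) and band-pass (1–40 Hz) filters are 4th-order
Butterworth applied forward-backward (zero-phase), preserving cross-channel
phase for the coherence stage. The filter family and order are configurable;
zero-phase filtering was chosen because coherence analysis follows. The
common average reference is computed over the 30 analysis channels only
(mastoids are not scalp signals). The baseline window is the 5-s
pre-stimulus rest — the only pre-stimulus interval the protocol provides.
Trials whose baseline or stimulation window would cross a recording edge
are skipped with a warning, never zero-padded. No automatic epoch rejection
is performed; artifact removal (least-squares regression of a recorded
artifact waveform, with intercept) is opt-in.

## Image encoding

"Sampled per second" is implemented as 20 evenly spaced points per
one-second window (stride fs/20; exactly every 25th sample at 500 Hz) —
the only reading that reconciles a 1–20 point index with 1800 samples per
class. Decimation is plain stride sampling without an extra anti-alias
stage: the 1–40 Hz band-pass already limits content, and residual 10–40 Hz
aliasing folds band power into the retained samples without destroying the
variance structure the classifier uses. The pixel map is element-wise
min-max scaling of the whole matrix onto [0, 255] (global, not per-channel),
rounded half away from zero; a constant matrix encodes to all zeros with a
warning. The scaling is strictly element-wise: summing the scaled terms
over channels and points would collapse the image to a single value and
could not produce per-pixel intensities, so no summation variant is
offered. "RGB" is grayscale replicated to three identical
planes; no colormap is invented.

## Classifier

No deep-learning framework is assumed: the CNN is implemented directly in
numpy (im2col convolutions, batch normalization, manual backpropagation,
Adam), which keeps training bit-deterministic given the seed. Two scales
exist:

* **full** — 14 residual modules containing 3 standard and 33
  depthwise-separable convolution layers (stem of 3 standard convs; three
  downsampling entry modules of 2 separable convs; eight identity-shortcut
  middle modules of 3; an exit module of 2; one final separable conv), with
  nearest-neighbor input resize to 71 × 71. It is constructible and
  forward-capable but is not trained in the desk-scale studies.
* **mini** — one stem convolution plus two separable residual modules,
  accepting native channels × points inputs. All trained results in the
  tests and pipeline use this scale. Default training: Adam, lr 1e-3,
  30 epochs, batch 32 (the dynamic-FC study uses lr 3e-3, 40 epochs,
  batch 8, appropriate to its 30-sample folds).

Cross-validation is stratified at the *sample* level: per class, five
near-equal parts rotate through train (3) / validation (1) / test (1), so
every sample is tested exactly once. Sample-level splitting is the default and
leaks subject identity across folds; passing subject ids as groups (the
pipeline's `split_by: subject` option) keeps each subject's samples in a
single role per fold. HVA is the positive class throughout;
metrics with zero denominators are reported as undefined (None), never 0.

## Channel selection

Each level evaluates every leave-one-out subset exhaustively — the only
scheme under which the selection grid can report one accuracy per
removable channel per level. Ties are broken toward
removing the channel with the larger montage index, deterministically. The
same fold seed is reused across subsets so all comparisons share folds. The
best subset may come from any level.

The evaluator is pluggable (`subset → accuracy`). Pixel-level linear
classifiers are structurally blind to the generator's power contrast (a
zero-mean variance difference), and the CNN evaluator is too expensive to
drive the 279-evaluation greedy-vs-exhaustive comparison at desk scale, so
the selection studies use a `var` evaluator: fivefold-CV logistic
regression on per-channel log-variance features — the classic band-power
wrapper evaluator in EEG channel selection. The CNN and pixel-level
baselines remain available as evaluator kinds.

## Connectivity estimator

Eq.-style magnitude coherence is estimated Welch-style with 1-s Hann
segments at 50% overlap (39 segments per 20-s trial), demeaned per segment,
and band-averaged over 1–40 Hz — the full filtered band, the only frequency
range the analysis names. Magnitude (not squared) coherence is the
pairwise statistic. The Fisher r-to-z transform is applied to magnitude
coherence before averaging and paired testing, a common convention in the
emotion-FC literature; coherence is not a Pearson correlation, so the
transform is a convention here rather than exactly variance-stabilizing. Off-diagonal means use the upper triangle only (28 values
for 8 channels). Unit coherences are clipped to atanh(1 − 1e-12) with a
warning before the z-transform. A single-segment trial is rejected: its
coherence is identically 1 and carries no information.

The estimator has a positive bias floor for incoherent signals of roughly
sqrt(pi/(4K)) for K segments (≈ 0.20 at K = 19, ≈ 0.14 at K = 39); planted
targets and tests account for it.

## Desk-scale study conditions

The statistical studies in `emofc.studies` (used by the test suite and the
acceptance script) run at reduced problem sizes chosen as the package's own
desk-scale conditions:

* Protocol arithmetic runs at the full reference-protocol size
  (15 subjects, 32 channels, 500 Hz) — it is cheap.
* The coherence-recovery study uses a 200-s realization at 250 Hz, target
  0.8 (tolerance ±0.05 covers estimator bias plus sampling spread).
* The prefrontal-contrast study keeps 15 subjects and 6 trials/state per
  replicate but uses a 4-channel montage at 128 Hz with 1-s rests; the
  planted targets (0.25 vs 0.30) are population quantities independent of
  sampling rate. 100 replicates.
* The selection study uses 6 subjects × 5 trials × 20 s on the 8-channel
  frontal montage at 100 Hz, with a quadrupled-power contrast on
  {Fp1, Fp2, F7} so the planted subset is the population optimum; 5 seeded
  datasets, greedy vs exhaustive (all 246 subsets of size ≥ 2).
* The dynamic-FC study keeps 15 subjects on the 8-channel montage at
  128 Hz, with the 0.25/0.30 prefrontal plant stable across trials;
  10 seeded datasets, mini CNN on k = 1 vs k = 6 features.

## Known limitations

* The full-scale CNN is never trained end to end here; only its
  architecture and forward pass are exercised.
* Real-recording accuracies are out of scope (no such data ships with the
  package); the studies validate directional and structural claims on
  synthetic data instead.
* The generator's subjects are exchangeable; subject-level random effects
  would widen the paired-test null and lower the contrast detection rate.
* EDF export is 16-bit quantized; round-trips are exact only to the
  per-channel quantization step.
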