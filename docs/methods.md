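# Methods

## Problem setting

A segment is a 20-s, 250 Hz single-lead ECG trace (5000 samples, mV) from a
bedside patient monitor.  Quality is a three-way judgement: *acceptable*
(nearly flawless), *unacceptable* (QRS complexes indistinguishable anywhere
in the trace, or severe artefact), *uncertain* (mildly flawed; QRS locations
discernible throughout).  The practical question downstream is binary —
usable (acceptable + uncertain) versus not — which is why evaluation reports
both the 3×3 confusion matrix and its merged 2×2 form.

## Preprocessing

Fixed order, applied per segment:

1. **Exclusion.** A segment is discarded if every sample is blank or if any
   maximal blank run lasts strictly longer than 0.5 s (126+ samples at
   250 Hz; a run of exactly 125 is kept).  "Blank" covers exact zeros and
   NaNs — monitor gaps arrive as either.  The threshold is strict by choice:
   0.5 s is the stated limit, not inside it.
2. **Extreme-value zeroing.** Samples beyond ±5 mV (electrode artefacts can
   exceed ±100 mV) are set to 0.  NaNs inside kept segments are treated as
   zeros first.
3. **Single-zero interpolation.** An isolated zero whose two neighbours are
   nonzero is replaced by their midpoint.  Runs of two or more zeros and
   boundary zeros are left alone — they are genuine gaps, and interpolating
   them would manufacture signal.  All isolated zeros are interpolated, not
   only those created by step 2 (the superset is deliberate; dropouts from
   the transport layer look identical to clipping residue).

The chain never changes segment length, and afterwards no sample exceeds
5 mV in magnitude.  No denoising is attempted: the goal is to *grade*
segments, not rescue them.

## Features (43)

Peak detection runs on a 0.5–8 Hz zero-phase Butterworth bandpass (order 2,
applied forward and backward), which suppresses baseline drift and
high-frequency noise while preserving the R deflection; peak *positions*
come from the filtered signal, peak *amplitudes* from the unfiltered one.
The detector takes local maxima above an adaptive threshold — halfway
between the median and the 99th percentile of the filtered trace — with a
0.25 s refractory distance (240 bpm ceiling).  Detectors return peaks, never
troughs, and monitor leads occasionally invert polarity, so every feature
family is also computed on the negated signal (`_neg` variants).

Unless stated otherwise, statistics are computed per 4-s subsegment (five
per segment, nonoverlapping) and aggregated by mean and population standard
deviation.  Conventions fixed here, where the underlying definition admits
choices:

* **slopes** — first difference of the full segment.
* **peak z-scores** — standardised within the segment's own detected
  amplitudes.
* **autocorr** — normalised (demeaned) autocorrelation for lags 1..fs
  (1 s covers a full beat at ≥60 bpm), pooled over subsegments.
* **crosscorr** — full cross-correlation between each *adjacent* pair of
  subsegments (4 pairs), normalised by the L2 norms of the raw blocks
  *without* demeaning: with demeaning the sequence sums to zero identically
  and its mean carries no information.
* **he** — Hurst exponent by rescaled-range analysis: block sizes
  16…512 capped at half the subsegment, H = log-log slope of mean R/S.
* **dtw** — unconstrained dynamic-time-warping distance with
  absolute-difference cost between adjacent subsegments, after 10×
  decimation (quadratic alignment at full 1000-sample resolution buys no
  discriminative power at 25× the cost).
* **maxpower / meanpowerdiff / meanfreqdiff** — maximum of the one-sided
  FFT power spectrum per subsegment; the drift features are the standard
  deviation of the successive between-subsegment differences of that
  maximum's power and frequency.
* **STFT** — Hanning window of 100 samples with 50% overlap, one-sided
  magnitudes; `mean/std(abs(stft))` pool all entries; spectral entropy is
  the Shannon entropy (natural log) of each time frame's power-normalised
  spectrum, aggregated by standard deviation over frames.

Degenerate inputs (constant signal, fewer than two detected peaks, fewer
subsegment values than an aggregate needs) yield the sentinel 0 plus a
cleared validity flag, keeping the vector fixed at 43 entries for the
classifiers.  `select_k_best` ranks columns by the one-way ANOVA F statistic
(constant columns last).

Several `_neg` features are mathematically tied to their plain versions
under these definitions (autocorrelation, kurtosis, DTW and FFT power are
sign-invariant; skewness negates).  They are still computed and stored
independently: the registry mirrors the fixed 43-name interface, and the
redundancy is harmless to a forest.

## CNN input images

All three transforms map a 5000-sample segment to an (80, 100) matrix:
sliding raw-sample windows (length 10, step 5 → 999 windows → 9990 values,
uniformly decimated to 8000 and reshaped row-major), STFT magnitude
(frequency rows × time-frame columns resampled to the grid), and
nonoverlapping windowed-FFT magnitude.  The window arithmetic does not land
on 80 × 100 exactly; uniform decimation is the fixed convention, isolated in
one function so it can be swapped.  All transforms are deterministic,
shape-stable, and homogeneous of degree one in the input amplitude.

## Classifiers and training scheme

Training data are heavily imbalanced, so both families train with **balanced
resampling**: each of `n_repetitions` steps draws a fresh equal-sized random
sample per class (new draws from the abundant class every step), holds out
20% of the draw for validation, and records macro precision/recall.  The
returned model is the step checkpoint maximising validation
precision + recall.

* **Warm-start forest.** Bootstrap with out-of-bag scoring; the ensemble
  grows by `estimators_increment` (default 50) trees per step, so after the
  default 20 repetitions the forest has 1000 trees, the later ones fitted on
  later draws.  Checkpoint selection truncates prediction to the leading
  trees of the best step.  Tree-level hyperparameters stay at scikit-learn
  defaults.
* **2D CNN.** Three valid-mode convolution blocks with feature maps
  (100, 50, 25) and kernels (7, 5, 3) — the kernel sizes are the package's
  choice of "correspondingly decreasing" — each followed by leaky
  rectification (negative-side slope 0.002, the natural reading of a
  rectifier with an alpha parameter) and average pooling (10, 5, 3) at
  stride 3; then dense layers 128-64-32-16 with dropout (keep 0.5), a
  softmax head (2 or 3 classes), L2 weight decay 0.01 on convolution and
  dense weights, Adam at 0.001, batch size 50.  Softmax cross-entropy serves
  both the binary and 3-class heads (for two classes it coincides with
  binary cross-entropy).  Early stopping monitors the per-step validation
  loss and stops as soon as a step fails to improve it — mirroring the
  common framework default of zero patience — then restores the best
  checkpoint's weights; the patience is configurable.  The
  network is implemented directly in numpy (im2col convolutions, exact
  gradients verified against finite differences in the test suite); training
  is fully reproducible for a fixed seed.

Dropout placement (after each dense hidden layer) and input standardisation
(global mean/std of the training images) are the package's conventions.

## Decision logic

* **One-step:** argmax over the three class probabilities; exact ties break
  in the fixed order acceptable > unacceptable > uncertain.
* **Two-step:** step 1 decides acceptable vs other at probability threshold
  0.5 (ties to acceptable); only segments sent to "other" reach step 2,
  which decides unacceptable vs uncertain at 0.5.  The 0.5 thresholds are a
  package convention.  Step 1 is trained only on acceptable + unacceptable
  segments, step 2 only on unacceptable + uncertain.

`build_training_sets` provides the corresponding index routing with one-shot
balancing to the minority count; when the cascade trains its own estimators
it passes the class-filtered *unbalanced* pools instead, so the per-step
resampling inside each estimator keeps drawing fresh majority-class
examples.

## Evaluation

Confusion matrices use rows = truth, columns = prediction, order
acceptable / unacceptable / uncertain.  The merged 2×2 matrix collapses
acceptable + uncertain (usable) against unacceptable by block sums;
precision_j = cm[j,j]/colsum, recall_i = cm[i,i]/rowsum, accuracy =
trace/total.  Empty denominators yield NaN, never a silent 0, so degenerate
test sets cannot inflate averages.

## Synthetic data: what it emulates and what it does not

A beat is a sum of four Gaussian lobes (Q, R, S, T) placed at jittered beat
times (2% RR jitter); contaminations are additive sinusoidal wander,
Gaussian broadband noise, 50/60 Hz powerline interference, single-sample
extreme spikes (default 120 mV), two-sample pacing-like spikes, and zeroed
blank runs.  Labels follow a construction rule with thresholds in mV
(broadband noise RMS: acceptable ≤ 0.05, unacceptable ≥ 0.25; wander
amplitude: ≤ 0.3 / ≥ 1.5; any spike → unacceptable; a blank run or
mid-range contamination → uncertain).  With a 1 mV R peak these bounds mark,
respectively, contamination that is barely visible versus contamination that
drowns QRS onset/offset — but they are stand-ins for expert judgement, not
measured quantities, and are exposed as module constants.

Two samplers are provided: `generate_dataset` draws contamination levels on
a realistic continuum within each class band (classes touch at the
thresholds, as real data do), and `well_separated_dataset` keeps acceptable
nearly pristine and places both flawed classes far from it — the regime for
parameter-recovery checks.  Proportion-based requests round by flooring each
class and giving the leftover to the last (rarest) class.

What passing tests on these data do **not** show: robustness to real
electrode-motion artefact morphology, arrhythmias, electromyographic noise
spectra, or inter-annotator ambiguity of the uncertain class.  The synthetic
labels are exactly consistent with the generating parameters, so measured
accuracies here are upper bounds relative to expert-labeled hospital data.
A known consequence of the cascade on continuum data: step 1 absorbs some
mildly flawed (uncertain) segments into acceptable, trading uncertain recall
for acceptable recall — the trade the cascade exists to make.

A second deliberate interaction: segments whose only flaw is one or two
extreme (>100 mV) single-sample spikes are labeled unacceptable by the
construction rule, yet the ±5 mV clipping stage removes the spikes and the
interpolation stage heals the holes, leaving a nearly clean trace that still
carries the unacceptable label.  Training after preprocessing therefore sees
a strict-label gray zone and loses a few points of acceptable-class recall;
training on unclipped features separates the classes almost perfectly.  Real
expert-labeled data exhibit the same tension between strict labels and
aggressive cleaning.

## Problem sizes and numerical choices

Test-suite and acceptance runs use synthetic datasets of 2000 training /
1000 test segments at 95/2.5/2.5% imbalance over five seeds for the cascade
comparison, 500/300 segments for well-separated recovery, and 200 images per
class for the CNN smoke training with 5 forest repetitions and 2 CNN epochs
per step — sizes chosen so a full run completes in minutes on one CPU while
leaving the qualitative effects (cascade recall advantage, early stopping
within 20 steps) visible.  Floating-point conventions: population standard
deviations throughout; float32 inside the network; probability rows sum to 1
within 1e-6.

## Known limitations

* The peak detector is a generic adaptive-threshold local-maximum routine,
  not a clinically validated QRS detector; it is adequate for quality
  grading, where distorted detection on bad segments is itself the signal.
* CNN determinism is exact here (pure numpy), but results will not transfer
  bit-for-bit to GPU/BLAS-threaded frameworks.
* The WFDB record format is not read directly; import real data by writing
  the delimited-text store (`manifest.csv` + one value-per-row file per
  segment).
* No significance testing between architectures is included.
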