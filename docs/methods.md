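# Methods

This note documents the models, procedures and design choices behind
`eegensemble`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

Multiple institutions each hold a small set of annotated neonatal EEG
recordings that cannot be pooled.  Each institution trains a local
seizure detector on its own patients; a trusted agent holds the trained
models and, for new data, aggregates the detectors' per-segment seizure
probabilities into one consensus stream.  The package implements the
local detector, four aggregation schemes, the surrounding preprocessing
and evaluation pipeline, and a synthetic data generator so that every
stage is testable without clinical recordings.  Model exchange is modeled
as plain file exchange of serialized weights; no network protocol or
privacy mechanism is implemented.

## Preprocessing

Raw multi-channel EEG (µV) is converted to classifier input as follows:

1. **Bipolar montage** — output channel `k` is `anode_k − cathode_k`.
   The standard 18-channel double banana and the reduced 3-channel
   (F3-P3, F4-P4, P3-P4) montages ship as presets.
2. **Band-pass and resample** — 6th-order Chebyshev type II with stopband
   edges 0.5 and 16 Hz, applied forward–backward (zero phase, so event
   timing stays aligned with the 1 s annotation grid), then polyphase
   resampling to 32 Hz.  The stopband attenuation design parameter is
   exposed (default 40 dB).  Because the cutoffs specify the *stopband*
   edges, the response droops a few percent by 5 Hz; the filtering test
   measures the single-pass deviation rather than assuming a flat
   passband.
3. **16-bit rescale** — linear map of ±`full_scale_uv` (default 500 µV,
   covering plausible neonatal amplitudes) to ±32767 with clipping; the
   µV-per-unit scale is stored for recovery within one quantization step.
   The detector standardizes each channel of each segment anyway, so
   predictions are independent of the chosen full scale.
4. **Segmentation** — 16 s windows (512 samples at 32 Hz) on a 4 s stride
   anchored at recording start; every interior 4 s frame is covered by
   exactly four windows.  All intervals are half-open `[start, end)`
   seconds.
5. **Zero-voltage exclusion** — a segment is invalid if any channel holds
   a run of exactly-zero samples strictly longer than 1 s (> 32
   consecutive zeros at 32 Hz), emulating detached electrodes and
   recording pauses.  Invalid segments are excluded from training and
   evaluation and break frame-averaging runs.

## Annotations and labels

Experts label each second 0/1.  *Consensus* is the all-experts
intersection: a second is a consensus seizure only if every expert marks
it.  A 16 s window starting at `t` covers seconds `t..t+15`; it is a
training/evaluation *seizure* segment iff all experts mark all 16 seconds,
a *non-seizure* segment iff all experts mark none, and *excluded*
otherwise.  Duration comparisons are strict: a patient enters the
training pool only with a consensus event strictly longer than 16 s, and
predicted events strictly shorter than 10 s are discarded (a 10 s event
survives).  Consensus events are computed by intersecting per-second
masks first and then extracting runs.

## Detector

Three components:

* **Feature extractor** — applied to every channel independently with
  shared weights: four blocks of [Conv1d(kernel 5, valid) → BatchNorm →
  ReLU → MaxPool(2)] with 16, 16, 64, 64 filters, then global average
  pooling over time, giving a 64-dimensional feature vector per channel.
* **Channel attention** — scores `e_c = v·tanh(W f_c + b)` with a
  27-unit bottleneck, softmax over channels, weighted sum of the feature
  vectors.  The parameter count depends only on the feature dimension,
  so one trained model accepts any channel count, and the output is
  exactly invariant under channel permutation.
* **Output** — a fully connected 64→2 layer with softmax; the seizure
  probability is the class-1 output, thresholded at `p ≥ 0.5` (ties to
  seizure).

This configuration has exactly 29 352 learnable parameters, which serves
as the architecture checksum.  The published description of the network
fixes the three components and the total parameter count but not every
internal width; the convolution widths follow common small-EEG-CNN
practice and the attention bottleneck width (27) is the one free dial set
so that the total matches the published size.

Training: consensus-labelled segments only; the majority class is
subsampled without replacement to exact balance (an institution with no
seizure segments cannot train and raises).  Cross-entropy loss, Adam,
initial learning rate 10⁻³ halved every 10 epochs, 30 epochs, batch 32
(the scaled-down experiments use 10 epochs).  Weights are initialized
with fan-in-scaled uniform draws; batch-norm applies batch statistics in
training and running averages at inference.  Given a seed, training is
bit-reproducible.  The network core (convolution, batch norm, pooling,
attention, softmax, Adam, backpropagation) is implemented in NumPy inside
the package; gradients were verified against central differences at
machine precision.

## Aggregation schemes

With `p_i^j` the probability from model `j` and `y_i^j = [p_i^j ≥ 0.5]`:

* Majority vote `μ^MV = mean_j y^j`; mean `μ^M = mean_j p^j`.
* Weighted mean `μ^WM = σ(Σ_j w^j p^j + w_0)`: weights are fit by
  logistic regression (scikit-learn, L2, C = 1) on one randomly selected
  institution's own data, predicted by the other `R − 1` detectors; that
  institution's detector is excluded from the weighted-mean ensemble.
  The fit includes an intercept.  An intercept-free variant is available,
  but with class-imbalanced held-out data and all-positive probability
  features it has no way to push the majority class below 0.5 except by
  sign-mixing the weights, which inverts the combined prediction — so it
  is not the default.
* Dawid–Skene: classic two-class EM on the thresholded labels (the
  method is defined on categorical responses).  E-step
  `μ_i ∝ π Π_j a_j^{y_ij}(1−a_j)^{1−y_ij}` versus
  `(1−π) Π_j (1−b_j)^{y_ij} b_j^{1−y_ij}`; M-step `π = mean μ`,
  `a_j = Σ μ_i y_ij / Σ μ_i`, `b_j = Σ(1−μ_i)(1−y_ij) / Σ(1−μ_i)`.
  Posteriors are initialized from the majority vote, which also pins the
  label-swap symmetry.  Defaults: tol 10⁻⁶ on the largest posterior
  change, max 100 iterations, probabilities clipped at 10⁻¹⁰ from the
  boundary.  The observed-data log-likelihood is recorded every iteration
  and is non-decreasing.  Degenerate unanimous input returns the
  unanimous labels; `R = 1` is permitted and documented (posteriors
  follow the single rater's labels).

All four schemes use the same `≥ 0.5` final threshold.

## Evaluation

* **Segment metrics** (per patient, consensus-labelled segments only):
  SE, SP at 0.5, and AUC via the rank statistic with half credit for ties
  (scikit-learn's implementation; the test suite checks it against the
  package's own event/agreement oracles where applicable).  A patient
  with one class present has undefined AUC and is skipped in summaries.
* **Post-processing**: frame probability = mean of the (valid) 16 s
  segments covering each 4 s frame; threshold; drop events < 10 s.
* **Event metrics**: SDR = fraction of consensus events overlapped by at
  least one predicted event; a false detection is a predicted event with
  zero overlap against the union of *all* experts' events (overlap with a
  single-expert seizure is neither a detection nor a false alarm); FD/h
  normalizes by recording hours; MFDD is the mean false-detection
  duration, reported as 0 at patient level when there are none and
  skipped in cross-patient summaries (like undefined AUC).
* **Agreement**: Gwet's AC1, robust to the class imbalance typical of
  seizure data; the implementation is tested against a brute-force
  transcription on exhaustive small matrices.
* Summaries are means and medians over patients with defined values.

## Experiment design

The training pool contains patients with a consensus seizure longer than
16 s.  `partition_patients` shuffles the pool, deals three patients to
each of `k` institutions and assigns the remainder uniformly at random —
subsets are disjoint, cover the pool, have at least three patients each,
and differ in size, which is what makes local detectors differ in
generalization strength.  Leave-one-subject-out folds, repeats, and the
random stacking-institution selection are all derived from a master seed
via per-job hashing (repeat → fold → institution), so any single job is
reproducible in isolation.  `count_jobs` gives closed forms that the
tests check against explicit enumeration; at the full design (10 repeats,
38 folds, k = 3..10) they give 19 760 local detectors and 3 040 stacking
fits, and 521 detectors / 80 fits for the external-test plan.
`run_experiment` executes one protocol instance with optional job-level
model caching (keyed by a hash of patients, architecture, training
config and seed) and a dry-run mode.

## Synthetic data generator

The generator emulates the *structure* of the clinical corpora, not their
physiology: per-channel colored (1/f-like) Gaussian background at
~30 µV RMS; seizures as 1–4 Hz rhythmic discharges with two harmonics and
raised-cosine on/off ramps, added on `ceil(fraction × channels)` random
channels; event counts Poisson at the configured hourly rate, placed
without overlap and with ≥ 10 s gaps so post-processing cannot merge
distinct truth events.  The discharge fundamental and the background
spectral tilt are drawn once per patient, giving the cohort-to-cohort
variability that makes a detector trained on three patients transfer
imperfectly to unseen ones — the mechanism the ensemble is meant to
absorb.  Experts are simulated by dropping each true event with a miss
probability and jittering kept boundaries with truncated Gaussian noise
at 1 s label resolution.  A separate rater simulator emits hard labels
through known per-rater sensitivity/specificity and probabilities near
the hard label, for validating the aggregation schemes against known
ground truth.

Passing tests on this generator demonstrate that the pipeline's logic and
arithmetic are correct and that the ensemble mechanisms behave as
designed on separable data; they do not show clinical-grade performance
on real neonatal EEG, which contains artifacts (respiration, ECG),
non-stationary background, and far more diverse seizure morphology.

## Problem sizes

The scaled-down ensemble-benefit experiment uses 11 synthetic patients of
45 min each (four channels at 64 Hz acquisition), nine forming three
institutions of three and two held out for testing, ≈ 2 000 segments per
institution, a reduced detector (two conv blocks of 8 and 16 filters,
930 parameters), 10 training epochs, and five master seeds.  These sizes
were chosen so the whole study runs in minutes on a single CPU while
preserving the design's structure; the reference 29 352-parameter
architecture is exercised in building, counting, prediction and
serialization tests, and trains with the same code path.

## Known limitations

* The NumPy network trains on CPU only and is sized for desk-scale
  experiments, not the full clinical corpus.
* Synthetic EEG omits artifacts and realistic morphology (see above), so
  absolute metric values on it are optimistic.
* The Dawid–Skene EM consumes thresholded labels; probability-aware
  variants are out of scope.
* Only the zero-voltage rule performs artifact rejection; no other
  channel-quality screening is implemented.
* EDF files can be read (via mne, optional) but not written; the
  package's own npz container and CSV tables are the interchange formats.
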