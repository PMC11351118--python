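# Methods

## The problem

A swallowed capsule endoscope records 8–13 hours of video at an adaptive
2–6 frames/s while it transits stomach → small intestine → colon. Knowing
*where* the capsule is matters clinically: gastric retention beyond one
hour calls for intervention (prokinetics or endoscopic delivery), and
20–30% of studies end before the capsule reaches the colon ("incomplete
study"). Frame-wise organ classifiers rely almost entirely on color and
fail when food debris, bubbles or fecal material make a frame's color
misleading. The pipeline implemented here adds temporal context (an LSTM
over CNN features) and a causal smoothing/boundary-detection stage so that
organ entry times can be estimated from a live stream.

## Model

**Stage 1 — frame features.** Each preprocessed frame `i_j` is mapped to a
feature `x_j = GAP(f_backbone(i_j))`, the global-average-pooled output of a
convolutional backbone, with a linear softmax head on top. The loss is the
per-frame cross-entropy `L_cnn = −log p(y_j)`. Training uses
Sharpness-Aware Minimization (rho 0.05, two gradient evaluations per step)
over SGD with momentum 0.9, batch 32, with color-jitter augmentation
(probability 0.8), grayscale and horizontal flip (0.5 each), right-angle
rotations, and Mix-up (Beta(0.2, 0.2) convex combinations with soft
labels). Two backbones are provided: `tiny` (three stride-2 3×3 conv
blocks, 32-dim features, for 64×64 desk-scale frames) and `standard`
(stride-2 stack ending in a 1×1 conv, 1280-dim GAP features at 512×512,
the width of an EfficientNet-B0-class extractor). Both are implemented
natively in NumPy (im2col convolutions with full backpropagation); the
package has no deep-learning-framework dependency.

**Stage 2 — sequence head.** The classifier head is removed, the backbone
is frozen (its parameters are bit-identical before and after this stage;
the test suite checks this), and a 5-layer LSTM with 64 hidden units runs
over 32-frame feature windows. The recurrent output `h_j` is projected
(64→3) through softmax to give `o_j`; the loss is the *sum* of the
per-frame cross-entropies over the window, optimized with Adam at batch
size 1. `o_j` depends only on frames 1..j — strict causality, verified by
perturbation tests. The hidden state is reset at each window by default
(carrying it across windows is available but off, matching the
batch-of-one 32-frame training regime).

**Calibration and boundaries.** Raw argmax paths bounce. The per-class
probabilities are smoothed with a *causal half-Gaussian* kernel
`w_i ∝ exp(−i²/2σ²)` over the current and `window−1` past frames
(default window 128, chosen by the validation grid search implemented in
`sweep_calibration`; σ defaults to window/4 so the kernel decays to ~0
inside the window). Smoothing probabilities rather than integer class
indices keeps every output on the simplex. The smoothed argmax path is
scanned by a monotone stomach → SI → colon state machine: a transition
commits at the first frame ≥ `skip_frames` (default 512, excluding
start-of-video artifacts) where the path equals the next organ and holds
for `persistence` frames (default 1). The machine never moves backward —
anatomical ordering is irreversible for a swallowed capsule — and advances
one organ at a time. Gastric transit = SI entry − start; small-bowel
transit = colon entry − SI entry; gastric time > 60 min raises the
retention alarm; a missing colon entry marks the study incomplete.

## Preprocessing

Native 576×576 frames are center-cropped to 512×512 (the border carries
burned-in device text; odd margins floor-split), every fifth frame is kept
(1-in-5 temporal downsample, applied before labeling from timestamps), and
videos are cut into consecutive non-overlapping 32-frame windows. Final
partial windows are kept for inference (every frame needs a prediction)
and dropped for LSTM training (fixed-length batching). Frame indices are
0-based.

## Synthetic data

Patient video is not redistributable, so the generator fabricates videos
with the structural properties that matter to the pipeline:

- three ordered organ segments with organ-specific color/texture
  (stomach: smooth pink-red; small intestine: high-frequency yellow-orange
  speckle; colon: darker brown-green with dark blobs) plus Gaussian pixel
  noise — color is the primary learnable signal, mirroring why classical
  methods fail;
- per-frame intervals uniform in [1/6, 1/2] s (the 2–6 fps adaptive band);
- debris frames (default rate 0.2) whose appearance is drawn from a
  *different* organ's distribution: a nearest-mean-color oracle scores
  >95% on clean frames and <50% on debris frames, so sequence awareness is
  the only route to high debris accuracy;
- exact ground-truth transition timestamps, and a configurable fraction
  (default 0.2, matching the reference test prevalence of 14/72) of
  incomplete studies truncated in the distal small intestine;
- default organ dwell times (16, 60, 8) min with ±15% per-video jitter,
  putting the small-intestine frame share at ~71% (inside the documented
  70–80% band) and yielding ~3,000 downsampled frames per video — the
  desk-scale stand-in for 8–13 h recordings;
- cohort stratification over five pathology-like categories in the
  reference proportions (46/20/30/15/15), split development:test 2:3 per
  stratum (1:1 for "normal"), train:validation ≈ 4:1 inside development.

Everything is bit-deterministic given the config seed; frames are
re-rendered on demand from (seed, frame index) so videos cost no storage.

What the generator does **not** emulate: real endoscopic texture, lesions
(pathology strata affect only cohort grouping), lighting/peristalsis
dynamics, capsule stasis (e.g. duodenal-bulb retention producing repeated
pylorus images), or gradual bowel-preparation decay toward the distal
ileum. Passing tests therefore demonstrate that the pipeline recovers
boundaries when color+temporal structure carries the signal; they do not
certify clinical performance on patient video.

## Numerical choices

- Cross-entropy probabilities are clamped at 1e−12 before the log.
- Input normalization is fixed: `(x/255 − 0.5)/0.25`.
- Float32 parameters and activations; He/uniform initialization; LSTM
  forget-gate bias starts at 1.
- Early stopping monitors validation loss (patience 3) and restores the
  best-validation checkpoint; with no validation split the training loss
  is monitored instead.
- Learning rates default to 1e−3 (CNN/SGD) and 1e−4 (LSTM/Adam),
  configurable; the desk-scale study keeps these defaults at 5 epochs.
- Kernel truncation at the start of a trace renormalizes by the available
  weight, which preserves the simplex exactly.
- Grid-search ties in `sweep_calibration` break toward (fewer missed
  boundaries, smaller error, smaller window), in that order.
- MCC with a zero denominator factor is defined as 0; a per-class metric
  with an empty denominator (absent class) is reported as NaN, not 0.
- Micro-F1 is identically accuracy for single-label multiclass, so the
  headline "accuracy and F1" pair is (accuracy, micro-F1); macro-F1 is
  also emitted.

## Open design points resolved here

- The recurrent output equation `o_j = h_j` conflicts with `o_j` being a
  3-class prediction; resolved as h_j (64-d) → linear projection →
  softmax.
- Rotation set "0, 90, 180, 270 or 360 degrees" collapses to
  {0, 90, 180, 270} (0 ≡ 360).
- The 512-frame skip counts model-input (downsampled) frames; skipped
  frames still receive predictions, they are only excluded from the
  boundary search.
- Residual post-smoothing bounces are resolved by the persistence
  parameter of the state machine (default 1); this mechanism is this
  package's choice.
- The reported headline MCC/G-mean values in the study abstract disagree
  slightly with its per-class table; the table's definitions are
  implemented and recorded in `published.py`.

## The desk-scale study (`wcelocate.study`)

`run_synthetic_study(seed)` generates 12 videos at 64×64 under the default
conditions above, trains the tiny CNN then the LSTM for 5 epochs each,
predicts and calibrates all 12 videos and reports: per-video absolute
SI-entry error (typical median < 1 min against a ~36 s causal smoothing
lag), completeness agreement, debris-frame accuracy for both models (the
sequence model typically ≈ 0.95 vs ≈ 0.36 for the color-only CNN), and
Table-style per-class metrics on the test split. Problem sizes (12 videos,
~3,000 frames each, 5 epochs) are the package's desk-scale defaults so the
whole study runs in a few CPU-minutes. `scripts/acceptance.py` re-runs
this study from scratch and writes every measured quantity to JSON.

## Known limitations

- The NumPy training engine is single-threaded BLAS-bound and desk-scale;
  it is not meant to train 512×512 clinical-scale models.
- Pre-trained (noisy-student) backbone initialization is not bundled;
  backbones start from random initialization.
- Wilcoxon / Kruskal–Wallis comparisons of boundary errors are out of
  scope as bespoke code; the per-video error table is emitted so any
  statistics package can run them.
- The synthetic debris mechanism (wrong-organ appearance) is the simplest
  one that defeats a color-only classifier; real debris partially occludes
  frames and is temporally correlated.
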