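# Methods

## Problem and metrics

`ppgxai` evaluates whether a convolutional classifier for PPG
(photoplethysmography) signal quality *attends* to the same regions of the
waveform that a human expert marked as artifactual. A segment is a
fixed-length vector `x_i` (default: 30 s at 240 Hz with an inclusive final
endpoint, i.e. 7201 samples); the expert annotation is a binary per-sample
mask `z_i`; the model's attention `ẑ_i` is a nonnegative per-sample vector
derived from a saliency map. Two dataset-level metrics compare them.

**Congruence** of one record is the proportion of attention mass inside the
annotation,

    Cong(z, ẑ) = Σ_j z_j ẑ_j / Σ_j ẑ_j ∈ [0, 1],

and the dataset value is the unweighted mean over records. It is invariant
to positive rescaling of ẑ and says nothing about *coverage*: a single
attended pixel inside the annotation already yields congruence 1. Records
whose attention map is identically zero have an undefined congruence; they
are skipped with a logged warning (and an error is raised only if every
record is undefined).

**Annotation Classification** measures coverage. The signal is decomposed
into units; each unit is scored by its attention and labeled by the
annotation; the AUROC of score-thresholded label prediction, pooled over
the whole test set, is the metric. Three unit constructions:

- *pixel* — every sample is a unit (score `ẑ_ij`, label `z_ij`);
- *sectional* — maximal constant-annotation runs are units, scored by the
  maximum attention inside the run;
- *interval* — fixed-duration tiles (default 5 s) are units, scored by the
  maximum attention inside the tile and labeled positive if any annotated
  sample overlaps the tile.

AUROC is computed with the tie-corrected rank formula, which equals
brute-force Mann–Whitney pair counting (ties = 1/2) bit-for-bit; the ROC
curve itself comes from the standard threshold sweep where tied scores
cross the threshold jointly. Units are pooled across records into one ROC;
a per-record-then-average variant is deliberately not the default.

Interval tiling covers the segment *duration* `(n−1)/fs`, with the final
tile absorbing the inclusive endpoint sample: a 7201-sample segment tiles
into exactly six 5-s intervals rather than six plus a one-sample remainder.
A remainder genuinely shorter than the tile length is kept as its own unit
so no sample is ignored.

**Sectional bias.** Because sections are scored by their maximum, longer
sections are biased toward larger scores, and unannotated sections are
typically much longer than annotated ones. `section_length_summary` reports
mean section length per class so Sectional AUROC can be read with that
caveat.

Explainability metrics are computed on annotated (artifactual) records
only; unannotated records are excluded with a log line, since the metrics
are undefined without a mask.

## Saliency and attention post-processing

Attention is the elementwise absolute value of a signed attribution
(guided maps are already nonnegative and pass through unchanged). For 2D
(image-input) attributions the map is first reduced by taking the maximum
absolute value over the rows of each column, then length-matched to the
signal by nearest-neighbor index scaling.

- *Integrated gradients*: midpoint-rule quadrature over the straight path
  from a baseline (default: the all-zero signal) with 64 steps by default.
  Completeness `Σ attr = F(x) − F(baseline)` holds to O(1/steps); the test
  suite checks < 1e-3 relative error at 512 steps on small ReLU nets.
- *Guided backprop*: the backward pass of the probability output where each
  ReLU zeroes positions whose forward pre-activation was negative *and*
  positions whose incoming backward signal is negative; the final map is
  clamped at zero. On confidently-classified records this double masking
  can annihilate every path and produce an all-zero map — a real property
  of the method that the congruence-skip rule above absorbs.
- *Expected gradients* (the "difference-from-reference" route): integrated
  gradients averaged over a background of references (default: 16 all-zero
  signals with σ = 0.01 Gaussian jitter, seeded). Summation-to-delta
  `Σ attr = F(x) − mean_ref F(ref)` holds to the same quadrature accuracy
  per reference. Exact DeepLIFT-style multipliers are architecture-
  intrusive and no downstream metric distinguishes the two, so expected
  gradients stands in for the reference-based family; the method name
  "deepshap" is accepted as an alias.

## The classifier fixture

Since no deep-learning framework is assumed, the package carries a small
NumPy implementation of a residual 1D CNN: a stride-4 stem convolution,
`depth` residual blocks (each halving the length, with 1×1 strided
projections on the skip path), global average pooling, and a dense sigmoid
head. Convolutions are 'same'-padded im2col products; all forward passes
cache what the hand-written backward pass needs, and the backward pass
returns input gradients (the hook all three attribution methods use) as
well as parameter gradients. Gradients are verified against central finite
differences in the test suite.

Training follows the reference protocol by default: Glorot-uniform kernels
of size 80, binary cross-entropy, Adam at 1e-4, 50 epochs, and the weights
of the epoch with the best validation accuracy (earliest epoch on ties)
kept as the final model. The validation set is a stratified 20% split of
the training data unless given explicitly. The positive class is
*artifact-free*; sensitivity is computed over artifact-free records,
specificity over artifactual ones, and NPV = TN/(TN+FN). Rates with zero
denominators are reported as NaN, never silently as 0.

## Synthetic world

The generator emulates what the metrics need and nothing more:

- *Clean PPG*: a two-Gaussian beat template (unit-height systolic peak at
  30% of the beat, 0.35-height dicrotic bump at 65%) repeated with
  fractional period jitter (default 2%), plus 0.2 Hz baseline wander
  (amplitude 0.05) and white sensor noise (amplitude 0.01). Morphologically
  plausible, but no hemodynamics: no respiratory modulation, no
  amplitude-shape coupling, no inter-patient morphology families. A green
  test therefore establishes metric correctness, not clinical realism.
- *Artifacts*: gaussian-noise bursts, flatlines, spike bursts, or
  saturation clipping, placed without overlap; the returned onset/offset
  intervals delimit the corrupted samples exactly (half-open on the sample
  grid) and the signal outside them is bit-identical to the clean input.
  The default amplitude (4× signal SD) makes the classes easy, so the CNN
  fixture reaches high accuracy within seconds of CPU training.
- *Synthetic attention*: given a mask and a target congruence `p`, mass `p`
  is distributed over annotated samples and `1−p` over the rest
  (uniformly, with random weights, or as Gaussian bumps per run), so the
  measured congruence equals `p` exactly — the parameter-recovery oracle
  for the metric stack.

## Scaled defaults for trainable tests

The package default geometry stays 240 Hz / 7201 samples. Tests and the
acceptance script that *train* models use 30-s segments at 40 Hz (1201
samples), a reduced net (2 blocks, 8 channels, kernel 24), lr 3e-3 and
8–15 epochs so the full pipeline runs in seconds on one CPU. The
correlation study additionally uses weaker artifacts (amplitude 1.2×,
shorter episodes) and fewer epochs: on the easy world every model is
perfectly accurate and the performance vector is constant, which makes
Pearson correlation undefined; the harder world restores the accuracy
spread that varying the training-set fraction (5–50%, several repetitions)
is meant to induce. The study's saliency method defaults to integrated
gradients because guided backprop's all-zero maps can leave a model without
a defined congruence.

## Numerical choices and edge cases

- Annotation times (seconds) convert to indices by `floor(t·fs)` with a
  1e-9 guard against float representation of exact grid products; all index
  ranges are half-open `[start, end)` to prevent double counting.
- Overlapping annotation intervals are rejected, not merged — they signal
  annotation-file errors.
- AUROC with a single class of units raises a degenerate-AUROC error;
  cells of a comparison grid that would be degenerate are set to NaN and
  flagged, and summary arithmetic refuses incomplete grids.
- Pearson correlation requires n ≥ 3 and non-constant vectors; the study
  report records the effective n per row after dropping undefined
  performance values, and marks significance against the
  Bonferroni-adjusted level α/m (α = 0.05, m = 6 report rows).
- All randomness (waveform seeds, artifact placement, attention profiles,
  training shuffles, background jitter, study subsampling) flows through
  explicit integer seeds; derived seeds stay below 2³¹.

## Known limitations

- The guided-backprop map of a well-trained confident model is often
  sparse or empty; congruence comparisons across methods should check the
  logged skip counts.
- Expected gradients inherits quadrature error from its per-reference
  integration; summation-to-delta accuracy is relative to the output delta
  and degrades when the delta is near zero.
- The synthetic world's artifacts are statistically obvious by
  construction; results on it say nothing about performance on clinical
  recordings.
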