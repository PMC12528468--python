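# Methods

## Model

SurBiRa predicts an uncensored patient's survival time (days) from their
pathology slides in four cascaded stages.  The problem is weakly
supervised: the only label is the patient-level time of death, broadcast
to every tissue patch of every slide of that patient.

**Patch regression (Survpatch).**  Each slide is tiled into non-overlapping
S×S×3 patches restricted to tissue; each patch x is mapped to a scalar
y = f(c + Σ x·w) with a linear output activation f.  The architecture is
four [3×3 convolution → ReLU → 2×2 max-pool] blocks with channel widths
(8, 16, 24, 32), global average pooling, a 32→16 dense layer with ReLU,
and a 16→1 linear head — 12,361 trainable parameters, independent of the
input size because of the global pooling, and checked at build time
against a hard budget of 33,000.  Training: Adam (default moments), mean
absolute error loss on labels in raw days, 50 epochs by default, learning
rate 0.001·0.9^epoch, batch size 32, per-epoch shuffling and on-the-fly
augmentation (random contrast/gamma/brightness, each with probability 0.5,
magnitudes U[0.8,1.2], U[0.8,1.2], U[−0.1,0.1]).  All of it is seeded.

The output bias is initialized to the mean training label.  With an
absolute-error loss the gradient has unit magnitude, so Adam moves each
parameter by roughly the learning rate per step; starting from zero, a
model could never bridge a several-hundred-day offset within a realistic
step count.  Mean-bias initialization makes the untrained model the
constant mean predictor — the MAE optimum among constants — and leaves
gradient descent the job of learning *deviations*, i.e. the ordering
signal that the later stages and the concordance index actually consume.
Labels themselves are never transformed: all downstream arithmetic
(binning, forest, averaging) operates in days.

**Bin generation.**  A slide with n patch predictions gets a bin count by
the Freedman–Diaconis rule, m = n^(1/3)(max−min)/(2·IQR), with the IQR
from linear-interpolation quantiles, rounded half-away-from-zero and
clamped to ≥ 1 (m = 1 when the IQR or range degenerates to zero).  The
slide is summarized by the per-bin means of its predictions over m
equal-width bins spanning its own [min, max] (last bin right-closed,
computed with `scipy.stats.binned_statistic`).  Empty bins are filled
with the slide's overall mean prediction, which keeps features finite and
on the same scale.  Because the rule yields a different m per slide but a
forest needs fixed-length inputs, the model stores one global m — the
median of the training slides' per-slide counts, rounded up, clamped to
≥ 2 — and applies it to all slides, train and test.

**Slide regression.**  A random forest (10 trees, absolute-error split
criterion, bootstrap, seeded) maps the binned feature vector to the slide
survival SV_i.  Forest predictions are averages over tree-leaf values of
training survival times, hence always inside [min, max] of the training
times.  Note a subtlety of absolute-error trees: a leaf predicts the
*median* of its training samples, so a single-leaf forest returns the
median rather than the mean of the training times; the two coincide for
symmetric label sets, and the distinction vanishes for grown trees whose
leaves are nearly pure.

**Patient averaging.**  SV_p is the unweighted arithmetic mean of the
patient's slide predictions.

## Evaluation

MAE is the mean of |t − SV_p| in days.  The concordance index is the
uncensored special case: over all patient pairs with distinct observed
times, a pair scores 1 if the predicted ordering matches the observed
one, 0.5 if the predictions tie, 0 otherwise; pairs tied in observed time
are excluded from the denominator.  It is computed on predicted survival
time directly (longer predicted ↔ longer observed), and it is undefined
(raises) below two subjects or when all observed times tie.

Cross-validation is patient-grouped: patient ids are shuffled with the
seed and dealt round-robin into k folds, so fold sizes differ by at most
one and all slides of a patient stay together.  Per-fold metrics and the
pooled metrics over the concatenated held-out predictions (each patient
predicted exactly once) are both reported, since averaging-versus-pooling
is a genuine free choice.  Group comparisons use a two-tailed permutation
test on the difference of mean per-patient errors (assumption-free, seeded,
10,000 permutations by default, add-one smoothing so p is never zero).
Cross-cohort evaluation refuses overlapping patient ids.

The cascade ablation evaluates three prediction paths on identical folds
and seeds, reusing one trained patch model per fold: (1) the direct mean
of a patient's patch predictions; (2) binning, with each slide predicted
by the mean of its feature vector; (3) the full cascade.

## Synthetic cohorts

The generator emulates the *structure* the method depends on, not
histology: per patient a latent risk r ~ U[0,1] and survival
t = clip(baseline − effect·r + N(0, σ), 1, ∞) rounded to days (defaults
baseline 800 d, effect 600 d); 1-3 slides per patient with side lengths
jittered ±25% so tile counts vary; three tissue types with only primary
tumor informative.  A slide is a white background with an elliptic-blob
tissue region of pink stroma on which dark blue-purple elliptic "nuclei"
are rendered; for primary tumor their coverage (5%→40%) and darkness
scale monotonically with r, while lymph-node and normal/non-neoplastic
slides use the fixed midpoint texture regardless of r.  The generator
returns its exact rendering mask, which serves as ground truth for the
tissue detector.  An optional heavy-tail contamination mixes in long
uniform survival draws to mimic outlier-laden late-stage label
distributions.

What passing tests on these cohorts show: the cascade recovers a monotone
texture→survival signal through tiling, weak labels, binning, and the
forest, end to end, and degrades when signal-free slides are added.  What
they do not show: robustness to stain variability, scanner artifacts,
heterogeneous tumor morphology, or any other property of real H&E tissue
— the images are statistical stand-ins, not histology.

## Numerical and design choices

- **Tissue detection** (unspecified upstream): HSV saturation thresholded
  by Otsu with a fixed floor of 0.07 for degenerate (near-unimodal)
  images, near-white pixels (min channel ≥ 0.95) always background,
  followed by 5×5 morphological closing.  Achromatic uniform images are
  therefore deterministically all-background.
- **Tiling**: grid from (0,0) with stride = patch size (non-overlapping);
  partial edge tiles discarded; a tile is kept iff tissue coverage ≥ 0.5
  (configurable).
- **CNN engine**: implemented in NumPy (im2col convolution, explicit
  backprop, float32), gradient-checked against central finite differences
  in the suite.  Training is deterministic given the seed up to BLAS
  floating-point reduction order.
- **Desk-scale problem sizes**: the end-to-end suites and the acceptance
  script use 40 patients, 256-px slides, 64-px patches, at most 8 patches
  per slide (seeded subsample), and 15 training epochs; these sizes keep a
  full 5-fold run in the low minutes on one CPU while leaving the
  survival signal strongly recoverable.  The scientific defaults (512-px
  patches at 20×, 50 epochs, no patch cap) remain the package defaults.
- **Ties and degenerate inputs**: concordance ties as above; fold dealing
  breaks ties by the seeded shuffle; binning of a zero-range slide
  repeats the single value; forests require ≥ 2 slides.

## Limitations

- No stain normalization; the synthetic cohorts have no stain variation
  to correct.
- Pyramidal WSI reading is out of scope; flat PNG/TIFF images are assumed
  to be at the target magnification already.
- The forest interpretation of the slide-regression weights is the
  standard one (leaf averaging); alternative weighting schemes were not
  explored.
- Only scalar patch predictions are binned; binning a penultimate-layer
  feature channel is a possible extension, not implemented.
- All subjects must be uncensored; there is no censoring-aware loss or
  metric.
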