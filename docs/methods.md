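# Methods

## Model

`ocutax` classifies an RGB image against a two-level disease taxonomy with a
single network carrying one branch head per level.

**Backbone.** The default feature extractor is a stack of 3×3, stride-2
convolution + ReLU blocks (channel plan `(16, 32, 64, 128)`), ending in a
spatial feature map and a global-average-pooled feature vector of dimension
`D = 128`. The backbone contract — *final spatial map + pooled vector* — is
the only thing the rest of the system relies on, so any feature extractor
honoring it (e.g. a large pretrained CNN) can be plugged in; the default is
deliberately small enough to train on one CPU. The network and its training
loop run on a minimal reverse-mode automatic-differentiation engine over
NumPy arrays (`ocutax.autodiff`): tape-free, graph-walking, with exactly the
op set the model needs (strided conv via im2col, dense, ReLU, sigmoid,
global average pooling, concatenation, focal loss). Gradient correctness is
pinned by finite-difference tests.

**Heads.** Each branch is a stack of fully connected units (default widths
256, 128) ending in one **sigmoid output per class** of its level — sigmoid,
not softmax, because several diseases can be present at once and per-class
scores must be independently thresholdable. The level-1 branch consumes the
pooled backbone vector. The level-2 branch consumes the **concatenation of
the pooled vector with the level-1 branch's penultimate hidden activations**,
so the coarse decision conditions the fine one. Concatenating pooled vectors
(rather than pre-pooling spatial maps) was an open design point; pooled
concatenation is cheaper and keeps the two branches' receptive structure
identical. What flows between branches is the penultimate activation vector
— richer than the handful of level-1 logits, and still low-dimensional.

**Flat baseline.** The ablation comparator is the identical backbone and head
widths with the inter-level connection removed: independent per-class binary
classifiers at each level. It consumes the same inputs and emits identically
shaped outputs, so reports are drop-in comparable; a gradient-flow test
verifies its level-2 loss never touches level-1 branch weights.

Inference does **not** enforce hierarchy consistency (no masking of children
by parents). Violations — a subclass called positive while its parent is not
— are *reported* by `taxonomy.check_consistency` rather than corrected.

## Loss

Every (sample, class) cell is a binary problem scored with the focal loss
`FL(p_t) = −(1 − p_t)^γ log p_t`, `p_t = p` if `y = 1` else `1 − p`. With
`γ = 0` this is exactly binary cross-entropy; larger `γ` suppresses easy
cells so the heavily imbalanced rare classes keep contributing gradient.
Defaults and numerical choices:

* `γ = 2` — the canonical value from the focal-loss literature; configurable.
* reduction = **mean** over samples and classes, so the level weight `α`
  keeps its meaning regardless of how many classes a level has (sum
  reduction would implicitly re-weight levels by class count).
* probabilities clamped to `[ε, 1 − ε]`, `ε = 1e−7`, before the log; the
  analytic gradient is zeroed in the clamped region.
* no per-class weights beyond the focal modulator.

The total objective is the convex combination `Loss_T = α·loss_l1 +
(1 − α)·loss_l2` with `α ∈ (0, 0.5)` enforced (finer level dominates) and
`α = 0.3` by default, i.e. a 3:7 weighting. The boundary `α = 0.5` is
rejected by validation.

## Training schedule

Two stages, expressed as named presets:

| preset | input | stage 1 | stage 2 | optimizer |
|--------|-------|---------|---------|-----------|
| `full` | 299 px | 5 epochs, heads only, lr 1e−4 | 4 steps × 20 epochs, lr geometric 1e−4 → 1e−6 | Adam, eps 0.1 |
| `desk` | 96 px | 4 epochs, heads only, lr 3e−3 | 2 steps × 4 epochs, lr 1e−3 then 3e−4 | Adam, eps 1e−8 |

Stage 1 freezes the backbone bit-exactly (asserted in tests by byte
comparison). Stage-2 steps unfreeze backbone blocks cumulatively, **last
block first**; the number of steps defaults to one per block. The per-step
learning-rate sequence is geometric between the stated endpoints — the
schedule is "progressively reduced" and geometric interpolation is the
simplest scheme with that property; it must be strictly decreasing (config
validation). Each stage/step starts a fresh Adam state over the currently
trainable parameters. The `desk` preset exists so the full pipeline runs in
minutes on one CPU: smaller inputs, shorter stages, a larger learning rate
and the standard Adam epsilon (with eps 0.1 and lr 3e−3 the effective step
would be tiny on a freshly initialized small backbone). Batch size defaults
to 32.

Augmentation (on-the-fly, per draw, label-preserving): horizontal/vertical
flips at p = 0.5 each, rotation uniform in ±15°, brightness/contrast/
saturation jitter ±20%. Magnitudes are package defaults — modest enough not
to destroy the fine stripe textures that define level-2 classes. Augmentation
increases diversity; it does not rebalance class counts.

## Synthetic data

The generator emulates the *structure* of a clinical screening dataset, not
its appearance:

* **level-1 attribute (image-wide):** a background hue band evenly spaced on
  the color wheel per coarse class, plus a large centred motif
  (disc/ring/square/diamond cycling by class index) in a darker shade, and a
  mild vertical brightness gradient;
* **level-2 attribute (local):** a square "lesion" box (side = ⅓ of the
  image side, area fraction ≈ 0.11) placed uniformly at random, filled with
  hard black/white stripes whose orientation and spatial frequency encode
  the subclass within its parent;
* **imbalance:** geometric class counts, largest:smallest = 10:1 by default;
* **composites:** a configurable fraction of images (10% in the desk
  conditions) carries two level-2 labels; same-parent pairs share one
  background with two non-overlapping boxes, cross-parent pairs split the
  canvas into two hue bands with one lesion each. Labels are upward-closed,
  so cross-parent composites are multi-label at both levels;
* additive Gaussian pixel noise (sd 0.02 in [0,1] units) last; everything is
  deterministic given the seed.

The desk study conditions are 600 images at 96 px over a 2 level-1 × 4
level-2 fixture. By construction the level-1 problem is linearly separable
from raw pixel statistics at zero noise (a logistic-regression oracle on
mean/std RGB exceeds 0.9 accuracy — tested), so a failure to learn indicates
a training defect, not an unsolvable task. What passing these tests shows is
that the *mechanism* works end to end — hierarchy-consistent labels, focal
objective, staged schedule, multi-label calls, saliency localization. It
does **not** show clinical-grade performance: real slit-lamp and fundus
images have far subtler class boundaries, intra-class diversity, acquisition
artifacts and label noise that the generator deliberately omits.

## Evaluation

* Per-class ROC/AUC from sigmoid scores (AUC = Mann–Whitney rank statistic;
  ties count ½). A class absent from a split has its AUC flagged undefined
  rather than faked.
* Accuracy/sensitivity/specificity at the screening threshold; 0/0
  denominators are NaN-flagged.
* Per-level **confusion matrices use argmax** over the level's scores and
  only single-positive samples; multi-label composites are excluded from the
  matrix and their count reported. (ROC and the positive-call rule use
  per-class thresholds — the two views answer different questions.)
* Screening calls are **strictly greater than** the threshold (default 0.5);
  top-k lists are score-descending with ties broken by class order, and
  top-k correctness means the true class appears anywhere in the list.
* 5-fold cross-validation splits by image, seeded, fold sizes within 1 of
  each other; a grouped (per-patient) splitter would be the better practice
  when identity metadata exists. Fold ROC curves are aggregated by
  **vertical threshold-averaging** on a common FPR grid (labelled as such in
  the output, since pooled-score averaging is a defensible alternative).

## Saliency

Grad-CAM at the last convolutional block by default (overridable): channel
weights are the spatial mean of the class-logit gradient; the heatmap is
`ReLU(Σ_c w_c A_c)`, bilinearly upsampled and **max-normalized** to [0, 1];
an identically zero map stays zero rather than becoming NaN. The heatmap is
invariant to constant shifts of the output bias (gradients unchanged —
tested). Localization is quantified as the fraction of total heatmap mass
inside the ground-truth lesion box; a uniform map scores exactly the box's
area fraction, so values above it demonstrate genuine localization. On the
desk experiment the trained model's median localization score is ≈ 3× the
area fraction.

## Known limitations

* The default backbone is intentionally small; absolute performance on real
  imagery depends on plugging in a pretrained feature extractor satisfying
  the backbone contract.
* Level-3 taxonomy leaves are stored but no level-3 classifier is built.
* No inference-time hierarchy enforcement, no class-balanced focal variants,
  no label smoothing, no early stopping, no distributed training.
* The synthetic benchmark's composites with cross-parent pairs make level-1
  multi-label calls learnable but remain the hardest cases; per-image
  composite detection is reported as a rate rather than guaranteed.
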