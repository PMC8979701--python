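# Methods

This note documents the model, the synthetic benchmark, the numerical
choices and the known limitations of `accn`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Model and objective

The classifier is P(x) = softmax(F(G(x))): a convolutional feature
extractor G ending in global average pooling (features of dimension d_f)
and a single linear map F to class scores. Two backbones are provided,
both implemented in numpy with hand-written backprop: `tiny_cnn`
(three 3×3 conv blocks, strides 2/2/1, default widths 16/32/64, d_f = 64)
and `resnet_small` (conv stem + two downsampling residual blocks). The
training loop is backbone-agnostic; inputs are [0, 1] pixels centered by
−0.5 inside the forward pass so first-layer activations are roughly
zero-mean (without this, optimization on low-contrast images stalls).

Four loss terms are combined as L = L_lce + γ1 L_ac + γ2 L_gc + γ3 L_pce
with defaults (0.6, 0.3, 0.8):

* **L_lce** — cross-entropy over labeled raw images and their weak
  augmentations (one weak view per raw image per step).
* **L_ac** — squared Euclidean distance between the prediction on a raw
  unlabeled image (the anchor, treated as a constant) and each of its K
  strong views. The distance norm is configurable (`l2sq` default, `l1`
  available); squared L2 is the convention of the consistency-
  regularization literature this method belongs to.
* **L_gc** — mean squared distance between the global centroid memory and
  the batch-local soft-weighted centroids, over classes with non-zero
  batch weight. It is evaluated against the memory *before* that batch's
  update: computing it after would merely rescale every term by
  (1 − η_k)², measuring the same disagreement on an arbitrary scale.
* **L_pce** — cross-entropy against cluster pseudo-labels, over raw
  unlabeled images and their strong views (a view inherits its source
  image's pseudo-label).

All set-valued sums are reduced as means so the γ weights keep their
meaning across batch sizes. Cross-entropies are computed from log-softmax.
Pseudo-labels and anchors are constants (no gradient); gradients reach the
centroids in L_gc only through the features, with the soft weights held
fixed — letting gradients flow through the weights invites collapse of the
soft assignment itself.

## Clustering unit

Per batch: soft-weighted centroids c_k from the raw unlabeled features and
the classifier's softmax weights; damped memory update
M_k ← (1 − η) M_k + η c_k with η = e^(−t_k), where t_k is the number of
samples pseudo-labelled k in the *previous* batch — frequently seen
classes update slowly, rare classes snap to fresh evidence. Pseudo-labels
are assigned by nearest centroid (Euclidean, double precision, ties to the
smallest class index), by default against the updated memory
(`assign_from_memory`, switchable to the raw local centroids). A class
whose total soft weight falls below 1e-6 in a batch is flagged empty: its
centroid is backfilled from the memory, it is excluded from L_gc, and its
memory row is left untouched — at batch size 8 empty classes are routine,
and without the backfill they would produce NaN centroids. The memory is
seeded from the first batch's centroids (equivalently the t = 0, η = 1
full replacement), with L_gc = 0 on that step, rather than penalized
against an arbitrary initialization.

Two refresh policies govern the pce targets. `batch` (default) re-assigns
pseudo-labels every step — robust from the first clustering step onward.
`epoch` freezes the targets between full-pool refreshes at epoch
boundaries: at each epoch end the centroids are re-estimated over the
whole unlabeled pool, the memory is updated, and the pool is re-labelled.
Stable targets substantially reduce the label churn the classifier has to
fit, but freezing is only safe once the features are informative, so the
benchmark protocol pairs it with a supervised warm-up; a degeneracy guard
refuses to freeze an assignment in which any class is absent (training on
an all-one-class labelling is a collapse engine). The final
`pseudo_labels_` reported on the results object always come from one
fresh full-pool clustering pass under the returned network, so they are
consistent with the weights actually returned.

When the clustering unit is disabled (`disable_wcu`, the ablation
baseline), pseudo-labels are the softmax argmax kept above a confidence
threshold (default 0.95) and L_gc is dropped.

## Trainer protocol

Each optimizer step draws an independent labeled and unlabeled sub-batch
(8 each by default; roughly 40 images per step after augmentation
expansion). L_pce and L_gc switch on after `warmup_epochs` of
supervised-plus-consistency training: an untrained classifier's soft
weights are near-uniform, which collapses every soft centroid to the
global feature mean. The library default is one warm-up epoch; the
benchmark protocol (`benchmark_protocol`) uses ten — training the
clustering unit from an annotated-data baseline network rather than from
scratch — together with `epoch` pseudo-label refresh and best-epoch
selection by held-out validation accuracy. The optimizer is Adam at lr
0.001 (SGD + momentum available); no schedule.

One root seed fans out through `numpy.random.SeedSequence` to four
streams (initialization, labeled batching, unlabeled batching,
augmentation); the trajectory is bit-reproducible, and checkpoints capture
parameters, Adam moments, centroid memory and counts, batcher and RNG
states, so a save/resume run retraces an uninterrupted one exactly.
A non-finite loss aborts with a diagnostic carrying the epoch, step and
offending batch indices.

## Augmentations

Weak: random crop covering 80–100 % of the area (resized back, bilinear)
then horizontal flip with probability 0.5. Strong: RandAugment-style draw
of n_ops = 2 operators at magnitude 10 (0–30 scale) from the standard
14-operator pool, followed by Cutout with a quarter-side square filled
with neutral gray; K = 2 strong views per image. Geometric operators fill
exposed borders by edge reflection, avoiding black-corner artifacts a
classifier could shortcut on. Every operator is an exact or near-exact
identity at magnitude 0; the two parameter-free operators (autocontrast,
equalize) are blended with the original in proportion to magnitude/30 to
preserve that property. All randomness flows through the caller's
generator; there is no hidden global state.

## Synthetic benchmark

Real fundus datasets are deliberately not required. The generator draws
32×32 RGB images: a dark background with a reddish circular disc, plus a
class-specific pattern — a 5×5 lattice of small Gabor speckles (envelope
σ = 0.04 × size, spacing 0.14 × size) whose carrier frequency encodes the
class: 3 cycles/side for the normal class, 4 + 2k for abnormal class k.
Texture frequency, not position, carries the class — matching how lesion
*texture* separates fundus grades, and deliberately compatible with
translation-invariant (globally pooled) features. Patterns are zero-mean,
so a global exposure shift is orthogonal to every class-difference
direction. On top: i.i.d. Gaussian pixel noise (sd 0.1 in [0, 1] units),
optional per-image exposure jitter (brightness offset N(0, b), contrast
gain U(1−j, 1+j); defaults 0), clipping and 8-bit quantization.

`separation` is calibrated exactly: the whole-image L2 distance between
the closest pair of class-mean images equals separation × noise_sd, so
under the additive-Gaussian model the two-class Bayes error is
Φ(−separation/2) — separation 0 is chance, separation 6 nearly separable.
The calibration refers to the i.i.d. pixel noise only; exposure jitter
adds within-class variance beyond it (mostly orthogonal to the class
axis), and clipping/quantization perturb it marginally.

The standard benchmark (`make_benchmark`): 2 classes at separation 6,
10 labeled + 200 unlabeled per class for training, 200 test images from
an independent seed, plus a 100-image validation draw for model
selection. The unlabeled pool's true labels travel in a side channel used
only by evaluation code. Ablation variants all share the benchmark
protocol and a *matched optimizer-step budget* (one unlabeled-pool pass
per epoch, 30 epochs): in particular the supervised baseline gets the
same 1500 Adam steps as the full method — a baseline trained only until
its own small loader is exhausted would be undertrained and erratically
scored, and beating it would mean nothing.

What the generator does *not* emulate: vessel/lesion morphology,
inter-image registration differences, label noise, resolution in the
hundreds of pixels, and instance-level appearance variation beyond
exposure. Passing benchmarks therefore demonstrate the training mechanics
(consistency, clustering, memory, metrics) in a controlled regime — not
clinical performance.

Two regimes of the benchmark are informative. With exposure jitter off,
the task is sample-efficient: 20 augmented labels already train the
backbone close to its ceiling, and the semi-supervised gain is small
though consistently non-negative. With per-image exposure jitter on
(brightness sd 0.02, contrast jitter 0.1), invariance must be *learned*,
20 exposure draws cannot teach it, and the unlabeled pool plus strong-view
consistency yields a gain of several accuracy points over the supervised
baseline — the regime the method was designed for. The acceptance script
measures both.

## Numerical choices

* Distances and centroid memory in float64 (reproducible argmin
  tie-breaks); network parameters and activations in float32.
* Softmax/log-softmax always via the max-shifted stable form.
* Empty-class threshold 1e-6 of total soft weight.
* Convolutions by im2col + matmul; gradients checked against central
  finite differences (directional derivative converges as ε shrinks).
* PNG for images (lossless 8-bit round trip), CSV manifests, YAML config
  validated strictly (unknown keys rejected), npz checkpoints.

## Known limitations

* The nearest-centroid rule assumes roughly isotropic classes in feature
  space; under strong appearance nuisance its accuracy trails the linear
  classifier trained on the same features.
* t_k is a batch-level count, so η jumps between e^(−8) and 1 at batch
  size 8; very large batch sizes would freeze the memory (η → 0) and a
  different damping would be needed.
* The pseudo-cross-entropy inherits and can amplify class-prior skew in
  the pseudo-labels (confirmation bias); per-epoch frozen targets, the
  warm start and best-epoch selection mitigate but do not eliminate it.
* Binary metrics (SEN/SPE/AUC) treat one configurable class as positive;
  multi-class settings are evaluated one-vs-rest, and no ordinal-grade
  machinery is included.
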