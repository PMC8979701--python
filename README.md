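# accn — augmentation-consistent clustering for semi-supervised image classification

`accn` trains an image classifier from a *small* annotated set plus a
*large* unlabeled pool, the data situation typical of diabetic-retinopathy
(DR) screening: unlabeled fundus photographs are abundant, expert grading
is expensive. The package implements an augmentation-consistent clustering
network — consistency regularization between weak/strong augmentations
combined with a soft-weighted clustering pseudo-labeller backed by a damped
global centroid memory — together with a synthetic fundus-like benchmark,
an ablation harness, evaluation metrics (ACC/SEN/SPE/AUC, confusion matrix,
ROC) and a CLI. The neural network core (convolutional feature extractor,
linear classifier, Adam) is a compact, self-contained numpy implementation
with hand-written backprop, so everything runs on one CPU with no deep
learning framework.

## The method

A feature extractor G and a linear classifier F produce predictions
P(x) = softmax(F(G(x))). Labeled images x_i^l contribute a cross-entropy on
the set X^l of raw images and their weak augmentations (random crop +
horizontal flip):

    L_lce = mean −log P_y(x),   x ∈ X^l.

Each unlabeled image x_j^u is expanded into K strong views (RandAugment
draw + Cutout); its raw prediction is the *anchor* and the strong views are
pulled toward it:

    L_ac = mean ‖P(x_j^u) − P(x̃_j^u)‖².

The weight clustering unit pseudo-labels the unlabeled pool: per batch,
soft-weighted class centroids

    c_k = Σ_j δ_k(P(x_j)) G(x_j) / Σ_j δ_k(P(x_j)),

a damped global memory M_k ← (1 − η) M_k + η c_k with η = e^(−t_k)
(t_k = previous batch's class-k pseudo-label count), a global-consistency
penalty L_gc = (1/N_c) Σ_k ‖M_k − c_k‖², and nearest-centroid pseudo-labels
ŷ_j = argmin_k d(G(x_j), c_k) that feed a pseudo-cross-entropy L_pce over
raw unlabeled images and their strong views. The training objective is

    L = L_lce + γ1 L_ac + γ2 L_gc + γ3 L_pce,   (γ1, γ2, γ3) = (0.6, 0.3, 0.8),

minimized with Adam (lr 0.001, batch size 8 per stream).

## Worked example

Twenty labeled + 400 unlabeled synthetic fundus-like images (32×32, class
separation 6 noise-sd), trained for 30 epochs with the benchmark protocol
(10 supervised warm-up epochs, per-epoch pseudo-label refresh, best epoch
by validation accuracy):

```python
from accn import (ACCNModel, SyntheticSpec, benchmark_protocol,
                  generate_dataset, make_benchmark)

labeled, unlabeled, test = make_benchmark(seed=1)          # 20 + 400 + 200 images
val, _ = generate_dataset(SyntheticSpec(                   # model-selection split
    n_labeled_per_class=50, n_unlabeled_per_class=0,
    separation=6.0, seed=770002))

model = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                  config=benchmark_protocol(seed=1),
                  val_images=val.images, val_labels=val.labels)
results = model.fit()
print(results.summary())
print(results.evaluate(test.images, test.labels))
pseudo_acc = (results.pseudo_labels_ == unlabeled.true_labels).mean()
print(f"pseudo-label accuracy on the unlabeled pool: {pseudo_acc:.3f}")
```

prints

```
ACCN training results
====================================================
backbone            tiny_cnn (d_f=64)
classes             2
epochs x steps      30 x 50
optimizer           adam (lr=0.001)
gammas (ac, gc, pce) (0.6, 0.3, 0.8)
----------------------------------------------------
final-epoch mean losses:
  l_lce    0.1780
  l_ac     0.1369
  l_gc     0.0759
  l_pce    0.3564
  total    0.5680
best val accuracy   0.930 (epoch 28)
ACC 0.910  SEN 0.910  SPE 0.910  AUC 0.960
pseudo-label accuracy on the unlabeled pool: 0.900
```

A supervised baseline trained on the same 20 labeled images with the same
step budget reaches about 0.80–0.88 accuracy depending on the seed; the
nearest-centroid pseudo-labels recover ~90 % of the hidden truth of the
unlabeled pool. `run_ablation` / `accn ablate` rerun the method with the
consistency module or the clustering unit removed, over a labeled-budget
or positive-fraction sweep.

## Command line

```bash
accn generate --out data/ --classes 2 --seed 7        # synthetic dataset + manifest
accn train    --config cfg.yaml --out runs/exp1       # history, metrics, checkpoints
accn evaluate --checkpoint runs/exp1/net.npz --manifest data/manifest.csv --out m/
accn ablate   --variant no_wcu --variant no_acl --seeds 1,2,3 --out abl/
```

Datasets are a directory of PNGs plus a CSV manifest (`filename,label`,
label `-1` = unlabeled); hidden true labels of synthetic unlabeled samples
live in a separate side file that the trainer never reads.

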