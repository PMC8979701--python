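"""Class-structured synthetic fundus-like images.

The generator emulates the statistical situation of a small labeled set
alongside a larger (possibly class-imbalanced) unlabeled pool. Each class k
has a deterministic base pattern — a lattice of small Gabor-like speckles
whose carrier frequency is class-specific (coarse for the normal class,
finer for abnormal classes), drawn inside a dark circular "fundus" disc — and samples
add i.i.d. Gaussian pixel noise plus optional per-image exposure jitter
(brightness offset / contrast gain) on top.

``separation`` is calibrated in noise-standard-deviation units of the
*whole-image* Euclidean distance between class-conditional mean images:
for the closest class pair, ``||mu_i - mu_j||_2 = separation * noise_sd``.
Under the additive-Gaussian model (before clipping/quantization) the Bayes
error of the two-class problem is then Phi(-separation/2), which gives a
closed-form handle on task difficulty: separation 0 is chance, separation
6 is nearly separable.

Pixels are stored as 8-bit integers in [0, 255]; readers rescale to [0, 1].
Hidden true labels of unlabeled samples live in a side channel only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SyntheticSpec",
    "SyntheticSpecError",
    "LabeledSet",
    "UnlabeledSet",
    "generate_dataset",
    "write_manifest",
    "make_benchmark",
    "class_mean_images",
]

MANIFEST_NAME = "manifest.csv"
TRUTHS_NAME = "hidden_truths.csv"
UNLABELED_TOKEN = -1


class SyntheticSpecError(ValueError):
    """Invalid generator specification; message names the offending field."""


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 2
    n_labeled_per_class: int = 10
    n_unlabeled_per_class: int = 200
    image_size: int = 32
    separation: float = 4.0
    noise_sd: float = 0.1
    positive_fraction_unlabeled: float | None = None
    brightness_sd: float = 0.0    # per-image global intensity offset, N(0, sd)
    contrast_jitter: float = 0.0  # per-image gain, U(1-j, 1+j) about mid-gray
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise SyntheticSpecError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_labeled_per_class < 0:
            raise SyntheticSpecError(
                f"n_labeled_per_class must be >= 0, got {self.n_labeled_per_class}")
        if self.n_unlabeled_per_class < 0:
            raise SyntheticSpecError(
                f"n_unlabeled_per_class must be >= 0, got {self.n_unlabeled_per_class}")
        if self.image_size < 8:
            raise SyntheticSpecError(f"image_size must be >= 8, got {self.image_size}")
        if self.separation < 0:
            raise SyntheticSpecError(f"separation must be >= 0, got {self.separation}")
        if self.noise_sd <= 0:
            raise SyntheticSpecError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.brightness_sd < 0:
            raise SyntheticSpecError(
                f"brightness_sd must be >= 0, got {self.brightness_sd}")
        if not (0.0 <= self.contrast_jitter < 1.0):
            raise SyntheticSpecError(
                f"contrast_jitter must be in [0, 1), got {self.contrast_jitter}")
        p = self.positive_fraction_unlabeled
        if p is not None:
            if not (0.0 <= p <= 1.0):
                raise SyntheticSpecError(
                    f"positive_fraction_unlabeled must be in [0, 1], got {p}")
            if self.n_classes != 2:
                raise SyntheticSpecError(
                    "positive_fraction_unlabeled requires n_classes == 2 "
                    f"(got n_classes={self.n_classes})")


@dataclass
class LabeledSet:
    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class UnlabeledSet:
    images: np.ndarray       # (N, H, W, 3) uint8
    true_labels: np.ndarray = field(default=None)  # evaluation side channel only

    def __len__(self) -> int:
        return len(self.images)


def _base_disc(size: int) -> np.ndarray:
    """Dark background with a reddish circular disc, (H, W, 3) float."""
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - (size - 1) / 2.0, xx - (size - 1) / 2.0)
    inside = (r <= 0.48 * size).astype(np.float32)
    base = np.empty((size, size, 3), dtype=np.float32)
    for ch, tint in enumerate((0.55, 0.38, 0.25)):
        base[:, :, ch] = 0.05 + (tint - 0.05) * inside
    return base


def _unit_patterns(n_classes: int, size: int) -> np.ndarray:
    """Per-class Gabor-like patterns, each unit L2 norm over pixels/channels.

    Each class gets a Gaussian envelope at a class-specific position on a
    ring *and* a class-specific carrier frequency/orientation. The
    frequency difference matters: features pooled globally (translation
    invariant) can still tell classes apart, the way lesion *texture*
    rather than lesion position separates fundus grades.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    sigma, spacing = 0.04 * size, 0.14 * size
    grid = np.arange(5) - 2.0                     # 5x5 speckle lattice
    pats = np.empty((n_classes, size, size, 3), dtype=np.float64)
    for k in range(n_classes):
        # carrier frequency separates classes: 3 cycles/side for class 0,
        # 4+2k for class k>0 (wavelengths >= ~5 px survive 2x downsampling)
        freq = 3.0 if k == 0 else 4.0 + 2.0 * k
        orient = np.pi * k / n_classes
        p2 = np.zeros((size, size))
        for gi in grid:
            for gj in grid:
                by, bx = cy + gi * spacing, cx + gj * spacing
                env = np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2.0 * sigma ** 2))
                phase = 2.0 * np.pi * freq * ((xx - bx) * np.cos(orient)
                                              + (yy - by) * np.sin(orient)) / size
                p2 += env * np.cos(phase)
        pat = np.repeat(p2[:, :, None], 3, axis=2)
        pat -= pat.mean()  # zero-mean: class cue orthogonal to global brightness
        pats[k] = pat / np.linalg.norm(pat)
    return pats


def class_mean_images(spec: SyntheticSpec) -> np.ndarray:
    """Class-conditional mean images, (N_c, H, W, 3) float in [0, 1] scale.

    The blob amplitude is chosen so that the *closest* pair of class means
    is exactly ``separation * noise_sd`` apart in whole-image L2 distance.
    """
    base = _base_disc(spec.image_size).astype(np.float64)
    pats = _unit_patterns(spec.n_classes, spec.image_size)
    dmin = min(
        np.linalg.norm(pats[i] - pats[j])
        for i in range(spec.n_classes) for j in range(i + 1, spec.n_classes)
    )
    amp = spec.separation * spec.noise_sd / dmin
    return base[None] + amp * pats


def _render(means: np.ndarray, labels: np.ndarray, spec: SyntheticSpec,
            rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    imgs = means[labels] + rng.normal(0.0, spec.noise_sd, size=(n,) + means.shape[1:])
    if spec.brightness_sd > 0 or spec.contrast_jitter > 0:
        # acquisition variability: per-image exposure offset and gain, applied
        # about mid-gray; with zero-mean class patterns the offset is
        # orthogonal to every class-difference direction
        b = rng.normal(0.0, spec.brightness_sd, size=(n, 1, 1, 1))
        c = rng.uniform(1.0 - spec.contrast_jitter, 1.0 + spec.contrast_jitter,
                        size=(n, 1, 1, 1))
        imgs = 0.5 + c * (imgs - 0.5) + b
    return np.clip(np.rint(imgs * 255.0), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledSet, UnlabeledSet]:
    """Draw the labeled and unlabeled sets described by ``spec``.

    Bit-identical under the same spec. Hidden true labels of the unlabeled
    pool are returned for evaluation only; nothing in the trainer reads them.
    """
    rng = np.random.default_rng(spec.seed)
    means = class_mean_images(spec)

    lab_labels = np.repeat(np.arange(spec.n_classes), spec.n_labeled_per_class)
    lab_imgs = _render(means, lab_labels, spec, rng)

    if spec.positive_fraction_unlabeled is None:
        unl_labels = np.repeat(np.arange(spec.n_classes), spec.n_unlabeled_per_class)
    else:
        total = spec.n_classes * spec.n_unlabeled_per_class
        n_pos = int(round(spec.positive_fraction_unlabeled * total))
        unl_labels = np.concatenate([
            np.zeros(total - n_pos, dtype=int), np.ones(n_pos, dtype=int)])
    unl_imgs = _render(means, unl_labels, spec, rng)

    # shuffle so class blocks are not ordered on disk / in batches
    perm_l = rng.permutation(len(lab_labels))
    perm_u = rng.permutation(len(unl_labels))
    return (
        LabeledSet(lab_imgs[perm_l], lab_labels[perm_l]),
        UnlabeledSet(unl_imgs[perm_u], unl_labels[perm_u]),
    )


def write_manifest(labeled: LabeledSet, unlabeled: UnlabeledSet, out_dir) -> str:
    """Write PNGs + CSV manifest (label -1 = unlabeled) + hidden-truth side CSV.

    Returns the manifest path. The manifest never contains the unlabeled
    samples' true labels; those go to a separate file.
    """
    out_dir = os.fspath(out_dir)
    img_dir = os.path.join(out_dir, "images")
    try:
        os.makedirs(img_dir, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir!r}: {exc}") from exc

    rows, truth_rows = [], []
    for i, img in enumerate(labeled.images):
        fname = f"images/lab_{i:05d}.png"
        Image.fromarray(img).save(os.path.join(out_dir, fname))
        rows.append((fname, int(labeled.labels[i])))
    for j, img in enumerate(unlabeled.images):
        fname = f"images/unl_{j:05d}.png"
        Image.fromarray(img).save(os.path.join(out_dir, fname))
        rows.append((fname, UNLABELED_TOKEN))
        if unlabeled.true_labels is not None:
            truth_rows.append((fname, int(unlabeled.true_labels[j])))

    manifest_path = os.path.join(out_dir, MANIFEST_NAME)
    pd.DataFrame(rows, columns=["filename", "label"]).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows, columns=["filename", "true_label"]).to_csv(
        os.path.join(out_dir, TRUTHS_NAME), index=False)
    return manifest_path


def make_benchmark(seed: int, *, separation: float = 6.0,
                   n_labeled_per_class: int = 10,
                   n_unlabeled_per_class: int = 200,
                   n_test_per_class: int = 100,
                   image_size: int = 32, noise_sd: float = 0.1,
                   n_classes: int = 2,
                   positive_fraction_unlabeled: float | None = None,
                   brightness_sd: float = 0.0, contrast_jitter: float = 0.0):
    """The package's standard semi-supervised benchmark.

    Returns ``(labeled, unlabeled, test)`` where ``test`` is a LabeledSet
    drawn from the same class-conditional model with an independent seed.
    Defaults: 2 classes at separation 6 on 32x32 images, 20 labeled and
    400 unlabeled training images, 200 held-out test images.
    """
    train_spec = SyntheticSpec(
        n_classes=n_classes, n_labeled_per_class=n_labeled_per_class,
        n_unlabeled_per_class=n_unlabeled_per_class, image_size=image_size,
        separation=separation, noise_sd=noise_sd,
        positive_fraction_unlabeled=positive_fraction_unlabeled,
        brightness_sd=brightness_sd, contrast_jitter=contrast_jitter, seed=seed)
    test_spec = SyntheticSpec(
        n_classes=n_classes, n_labeled_per_class=n_test_per_class,
        n_unlabeled_per_class=0, image_size=image_size,
        separation=separation, noise_sd=noise_sd,
        brightness_sd=brightness_sd, contrast_jitter=contrast_jitter,
        seed=seed + 990_001)
    labeled, unlabeled = generate_dataset(train_spec)
    test, _ = generate_dataset(test_spec)
    return labeled, unlabeled, test
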