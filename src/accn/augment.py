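"""Weak and strong image augmentation policies.

The weak policy A_weak is a random crop (resized back to the input size)
followed by a random horizontal flip — the mild transform whose prediction
serves as the anchor. The strong policy A_strong^1..K applies a
RandAugment-style draw (n_ops operators sampled from a 14-op pool at a
shared magnitude) followed by a fixed sequence, by default Cutout with a
quarter-side square. Predictions on strong views are pulled toward the
anchor's prediction during training.

Conventions:

* images are (H, W, C) float32 in [0, 1]; every operator returns the same
  shape (crops are resized back);
* all randomness flows through the supplied ``numpy.random.Generator`` —
  no global state;
* geometric operators fill exposed borders by edge reflection, so no
  black-corner artifacts are introduced for a classifier to shortcut on;
* magnitude is on the usual 0-30 scale and every pool operator is an exact
  or near-exact identity at magnitude 0 (the two parameter-free operators,
  autocontrast and equalize, are blended with the original in proportion
  to magnitude/30 to preserve this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageEnhance, ImageOps
from scipy import ndimage

__all__ = ["WeakPolicy", "StrongPolicy", "AugmentationPolicy",
           "weak_augment", "strong_augment", "RANDAUGMENT_POOL"]

_MAX_MAGNITUDE = 30.0


@dataclass(frozen=True)
class WeakPolicy:
    crop_area: tuple[float, float] = (0.8, 1.0)  # crop covers this area fraction
    flip_prob: float = 0.5

    def __post_init__(self):
        lo, hi = self.crop_area
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"crop_area must satisfy 0 < lo <= hi <= 1, got {self.crop_area}")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError(f"flip_prob must be in [0, 1], got {self.flip_prob}")


@dataclass(frozen=True)
class StrongPolicy:
    n_ops: int = 2
    magnitude: float = 10.0
    fixed_sequence: tuple[str, ...] = ("cutout",)
    cutout_fraction: float = 0.25  # side of the erased square / image side

    def __post_init__(self):
        if self.n_ops < 0:
            raise ValueError(f"n_ops must be >= 0, got {self.n_ops}")
        if not (0.0 <= self.magnitude <= _MAX_MAGNITUDE):
            raise ValueError(f"magnitude must be in [0, 30], got {self.magnitude}")
        for op in self.fixed_sequence:
            if op != "cutout":
                raise ValueError(f"unknown fixed-sequence op {op!r}")
        if not (0.0 < self.cutout_fraction < 1.0):
            raise ValueError(f"cutout_fraction must be in (0, 1), got {self.cutout_fraction}")


@dataclass(frozen=True)
class AugmentationPolicy:
    weak: WeakPolicy = field(default_factory=WeakPolicy)
    strong: StrongPolicy = field(default_factory=StrongPolicy)
    K: int = 2  # number of strong views per unlabeled image

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")


# ---------------------------------------------------------------------------
# pixel/PIL conversion helpers


def _check_image(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image)
    if x.ndim != 3 or x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError(f"expected a non-empty (H, W, C) image, got shape {x.shape}")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32, copy=False)


def _to_pil(x: np.ndarray) -> Image.Image:
    return Image.fromarray(np.clip(np.rint(x * 255.0), 0, 255).astype(np.uint8))


def _from_pil(im: Image.Image) -> np.ndarray:
    return np.asarray(im, dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# weak augmentation


def weak_augment(image: np.ndarray, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> np.ndarray:
    """Random crop (resized back) then random horizontal flip."""
    x = _check_image(image)
    h, w, _ = x.shape
    wp = policy.weak

    area = rng.uniform(*wp.crop_area)
    side = np.sqrt(area)
    ch, cw = max(1, int(round(h * side))), max(1, int(round(w * side)))
    if ch < h or cw < w:
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        crop = x[top:top + ch, left:left + cw]
        x = _from_pil(_to_pil(crop).resize((w, h), Image.BILINEAR))
    if wp.flip_prob > 0 and rng.random() < wp.flip_prob:
        x = x[:, ::-1].copy()
    return x


# ---------------------------------------------------------------------------
# strong augmentation: RandAugment-style operator pool

def _frac(m: float) -> float:
    return float(m) / _MAX_MAGNITUDE


def _signed(v: float, rng) -> float:
    return v if rng.random() < 0.5 else -v


def _affine(x: np.ndarray, matrix, offset) -> np.ndarray:
    out = np.empty_like(x)
    for c in range(x.shape[2]):
        out[:, :, c] = ndimage.affine_transform(
            x[:, :, c], matrix, offset=offset, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _op_identity(x, m, rng):
    return x


def _op_rotate(x, m, rng):
    deg = _signed(30.0 * _frac(m), rng)
    out = np.empty_like(x)
    for c in range(x.shape[2]):
        out[:, :, c] = ndimage.rotate(x[:, :, c], deg, reshape=False,
                                      order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _shear(x, m, rng, axis):
    s = _signed(0.3 * _frac(m), rng)
    h, w, _ = x.shape
    if axis == 0:
        mat = np.array([[1.0, s], [0.0, 1.0]])
        off = [-s * (w - 1) / 2.0, 0.0]
    else:
        mat = np.array([[1.0, 0.0], [s, 1.0]])
        off = [0.0, -s * (h - 1) / 2.0]
    return _affine(x, mat, off)


def _translate(x, m, rng, axis):
    h, w, _ = x.shape
    size = h if axis == 0 else w
    shift = _signed(0.3 * _frac(m) * size, rng)
    off = [shift, 0.0] if axis == 0 else [0.0, shift]
    return _affine(x, np.eye(2), off)


def _blend(orig: np.ndarray, transformed: np.ndarray, alpha: float) -> np.ndarray:
    return np.clip((1.0 - alpha) * orig + alpha * transformed, 0.0, 1.0)


def _op_autocontrast(x, m, rng):
    return _blend(x, _from_pil(ImageOps.autocontrast(_to_pil(x))), _frac(m))


def _op_equalize(x, m, rng):
    return _blend(x, _from_pil(ImageOps.equalize(_to_pil(x))), _frac(m))


def _op_solarize(x, m, rng):
    thr = 1.0 - _frac(m)  # pixels above threshold are inverted; m=0 -> none
    return np.where(x >= thr, 1.0 - x, x)


def _op_posterize(x, m, rng):
    bits = 8 - int(round(4 * _frac(m)))  # m=0 -> 8 bits, identity
    if bits >= 8:
        return x
    return _from_pil(ImageOps.posterize(_to_pil(x), bits))


def _enhance(x, m, rng, enhancer):
    factor = 1.0 + _signed(0.9 * _frac(m), rng)
    return _from_pil(enhancer(_to_pil(x)).enhance(factor))


def _op_color(x, m, rng):
    return _enhance(x, m, rng, ImageEnhance.Color)


def _op_contrast(x, m, rng):
    return _enhance(x, m, rng, ImageEnhance.Contrast)


def _op_brightness(x, m, rng):
    return _enhance(x, m, rng, ImageEnhance.Brightness)


def _op_sharpness(x, m, rng):
    return _enhance(x, m, rng, ImageEnhance.Sharpness)


RANDAUGMENT_POOL = {
    "identity": _op_identity,
    "autocontrast": _op_autocontrast,
    "equalize": _op_equalize,
    "rotate": _op_rotate,
    "solarize": _op_solarize,
    "posterize": _op_posterize,
    "color": _op_color,
    "contrast": _op_contrast,
    "brightness": _op_brightness,
    "sharpness": _op_sharpness,
    "shear_x": lambda x, m, rng: _shear(x, m, rng, 0),
    "shear_y": lambda x, m, rng: _shear(x, m, rng, 1),
    "translate_x": lambda x, m, rng: _translate(x, m, rng, 1),
    "translate_y": lambda x, m, rng: _translate(x, m, rng, 0),
}


def _cutout(x: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    h, w, _ = x.shape
    side = max(1, int(round(fraction * min(h, w))))
    cy = rng.integers(0, h)
    cx = rng.integers(0, w)
    y0, y1 = max(0, cy - side // 2), min(h, cy + (side + 1) // 2)
    x0, x1 = max(0, cx - side // 2), min(w, cx + (side + 1) // 2)
    out = x.copy()
    out[y0:y1, x0:x1] = 0.5  # neutral gray fill
    return out


def _one_strong(x: np.ndarray, sp: StrongPolicy, rng: np.random.Generator) -> np.ndarray:
    names = sorted(RANDAUGMENT_POOL)
    for _ in range(sp.n_ops):
        op = names[rng.integers(0, len(names))]
        x = RANDAUGMENT_POOL[op](x, sp.magnitude, rng)
    for fixed in sp.fixed_sequence:
        if fixed == "cutout":
            x = _cutout(x, sp.cutout_fraction, rng)
    return x.astype(np.float32, copy=False)


def strong_augment(image: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """The K strong views A_strong^1..K(x), each same shape as the input."""
    x = _check_image(image)
    return [_one_strong(x, policy.strong, rng) for _ in range(policy.K)]
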