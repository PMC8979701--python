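"""The four training objectives and their balanced combination.

    L = L_lce + gamma1 * L_ac + gamma2 * L_gc + gamma3 * L_pce

* L_lce — cross-entropy on labeled images and their weak augmentations;
* L_ac  — augmentation consistency: squared Euclidean distance (L1
  selectable) between the prediction on a raw unlabeled image (the anchor,
  treated as constant) and each of its K strong views;
* L_gc  — global consistency: mean squared distance between the centroid
  memory and the batch-local centroids, over non-empty classes;
* L_pce — cross-entropy against cluster pseudo-labels over unlabeled raw
  images and their strong views (targets constant, no gradient).

All set-valued sums are reduced as *means* over samples/pairs so the
balance weights keep their meaning across batch sizes. Cross-entropies are
computed from log-softmax, never from probabilities. Each public loss has
a ``*_grad`` companion returning (value, gradient) for the trainer; the
plain functions take the representation named in their signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import log_softmax, softmax

__all__ = [
    "LossBundle",
    "lce_loss", "ce_from_logits",
    "ac_loss", "ac_grad_from_logits",
    "gc_loss", "gc_feature_grad",
    "pce_loss",
    "total_loss",
]

DEFAULT_GAMMAS = (0.6, 0.3, 0.8)


@dataclass(frozen=True)
class LossBundle:
    """The four loss terms, their balance weights, and the combined objective."""

    l_lce: float
    l_ac: float
    l_gc: float
    l_pce: float
    gammas: tuple[float, float, float] = DEFAULT_GAMMAS

    def __post_init__(self):
        for name in ("l_lce", "l_ac", "l_gc", "l_pce"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    @property
    def total(self) -> float:
        return total_loss(self.l_lce, self.l_ac, self.l_gc, self.l_pce, self.gammas)


def _check_labels(labels: np.ndarray, n_classes: int, what: str) -> np.ndarray:
    y = np.asarray(labels)
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValueError(
            f"{what} out of range [0, {n_classes}): min {y.min()}, max {y.max()}")
    return y.astype(np.intp)


def lce_loss(log_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean of -log p(true class) over the labeled set X^l (raw + weak views)."""
    lp = np.asarray(log_probs, dtype=np.float64)
    y = _check_labels(labels, lp.shape[1], "label")
    if lp.shape[0] != y.shape[0]:
        raise ValueError(f"{lp.shape[0]} rows of log-probs but {y.shape[0]} labels")
    if lp.shape[0] == 0:
        return 0.0
    return float(-lp[np.arange(len(y)), y].mean())


def pce_loss(log_probs: np.ndarray, pseudolabels: np.ndarray) -> float:
    """Pseudo-cross-entropy: structurally the lce with pseudo-label targets."""
    return lce_loss(log_probs, pseudolabels)


def ce_from_logits(logits: np.ndarray, labels: np.ndarray):
    """(loss, d loss / d logits) of the mean cross-entropy, fused/stable."""
    y = _check_labels(labels, logits.shape[1], "label")
    lp = log_softmax(np.asarray(logits, dtype=np.float64))
    n = len(y)
    if n == 0:
        return 0.0, np.zeros_like(logits, dtype=np.float64)
    loss = float(-lp[np.arange(n), y].mean())
    grad = np.exp(lp)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def _pairing(probs_raw: np.ndarray, probs_aug: np.ndarray,
             pair_index: np.ndarray) -> np.ndarray:
    idx = np.asarray(pair_index, dtype=np.intp)
    if idx.shape[0] != probs_aug.shape[0]:
        raise ValueError(
            f"{probs_aug.shape[0]} augmented rows but {idx.shape[0]} pair indices")
    if idx.size and (idx.min() < 0 or idx.max() >= probs_raw.shape[0]):
        raise ValueError("pair index out of range of raw rows")
    return idx


def ac_loss(probs_raw: np.ndarray, probs_aug: np.ndarray,
            pair_index: np.ndarray, norm: str = "l2sq") -> float:
    """Mean distance between anchor and strong-view prediction vectors.

    ``pair_index[r]`` names the raw row that augmented row ``r`` came from.
    ``norm``: 'l2sq' (squared Euclidean, default) or 'l1'.
    """
    p_raw = np.asarray(probs_raw, dtype=np.float64)
    p_aug = np.asarray(probs_aug, dtype=np.float64)
    idx = _pairing(p_raw, p_aug, pair_index)
    if len(idx) == 0:
        return 0.0
    diff = p_aug - p_raw[idx]
    if norm == "l2sq":
        return float((diff ** 2).sum(axis=1).mean())
    if norm == "l1":
        return float(np.abs(diff).sum(axis=1).mean())
    raise ValueError(f"unknown norm {norm!r}; use 'l2sq' or 'l1'")


def ac_grad_from_logits(logits_aug: np.ndarray, probs_anchor: np.ndarray,
                        pair_index: np.ndarray, norm: str = "l2sq"):
    """(loss, d loss / d logits_aug); the anchor is a constant (stop-grad)."""
    p_aug = softmax(np.asarray(logits_aug, dtype=np.float64))
    idx = _pairing(probs_anchor, p_aug, pair_index)
    m = len(idx)
    if m == 0:
        return 0.0, np.zeros_like(logits_aug, dtype=np.float64)
    diff = p_aug - np.asarray(probs_anchor, dtype=np.float64)[idx]
    if norm == "l2sq":
        loss = float((diff ** 2).sum(axis=1).mean())
        dp = 2.0 * diff / m
    elif norm == "l1":
        loss = float(np.abs(diff).sum(axis=1).mean())
        dp = np.sign(diff) / m
    else:
        raise ValueError(f"unknown norm {norm!r}; use 'l2sq' or 'l1'")
    # backprop through the softmax of the augmented rows
    dlogits = p_aug * (dp - (dp * p_aug).sum(axis=1, keepdims=True))
    return loss, dlogits


def gc_loss(memory: np.ndarray, local_centroids: np.ndarray,
            valid: np.ndarray | None = None) -> float:
    """Mean squared memory-to-local-centroid distance over valid classes."""
    mem = np.asarray(memory, dtype=np.float64)
    loc = np.asarray(local_centroids, dtype=np.float64)
    if mem.shape != loc.shape:
        raise ValueError(f"memory shape {mem.shape} != local shape {loc.shape}")
    if valid is None:
        valid = np.ones(mem.shape[0], dtype=bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        warnings.warn("all classes masked empty; global-consistent loss is 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    d2 = ((mem[valid] - loc[valid]) ** 2).sum(axis=1)
    return float(d2.mean())


def gc_feature_grad(features: np.ndarray, probs: np.ndarray,
                    local_centroids: np.ndarray, memory: np.ndarray,
                    valid: np.ndarray) -> np.ndarray:
    """d L_gc / d features, with the soft weights treated as constants.

    c_k depends on the features through the weighted mean, so
    d L_gc / d f_i = sum_k (2 / N_valid) (c_k - M_k) w_ik / W_k.
    """
    p = np.asarray(probs, dtype=np.float64)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.zeros_like(np.asarray(features, dtype=np.float64))
    w_total = p.sum(axis=0)  # W_k
    dl_dc = np.zeros_like(np.asarray(local_centroids, dtype=np.float64))
    dl_dc[valid] = 2.0 / n_valid * (local_centroids[valid] - np.asarray(memory)[valid])
    coeff = np.where(valid & (w_total > 0), 1.0 / np.maximum(w_total, 1e-300), 0.0)
    return (p * coeff[None, :]) @ dl_dc


def total_loss(l_lce: float, l_ac: float, l_gc: float, l_pce: float,
               gammas=DEFAULT_GAMMAS) -> float:
    """L = L_lce + gamma1 L_ac + gamma2 L_gc + gamma3 L_pce."""
    g1, g2, g3 = gammas
    if g1 < 0 or g2 < 0 or g3 < 0:
        raise ValueError(f"balance weights must be non-negative, got {gammas}")
    return float(l_lce + g1 * l_ac + g2 * l_gc + g3 * l_pce)
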