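"""Weight clustering unit: soft centroids, pseudo-labels, centroid memory.

Per batch, each class centroid is the feature average weighted by the
softmax probability the classifier assigns that class:

    c_k = sum_i delta_k(P_i) * f_i / sum_i delta_k(P_i).

Unlabeled samples are pseudo-labelled by the nearest centroid under the
Euclidean metric. A persistent per-class memory M_k smooths the batch-local
centroids with a damped convex update

    M_k <- (1 - eta) * M_k + eta * c_k,   eta = exp(-t_k),

where t_k counts how many samples were pseudo-labelled k in the previous
batch: well-populated classes update slowly, rarely seen classes snap to
fresh evidence. Distances and memory are kept in double precision so
tie-breaking and the closed-form update are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CentroidState",
    "soft_weighted_centroids",
    "assign_pseudolabels",
    "update_memory",
    "confidence_pseudolabels",
    "EMPTY_CLASS_EPS",
]

EMPTY_CLASS_EPS = 1e-6  # total class weight below this marks the class empty


@dataclass(frozen=True)
class CentroidState:
    """Global centroid memory {M_k}, previous-batch counts t_k."""

    memory: np.ndarray       # (N_c, d_f) float64
    counts: np.ndarray       # (N_c,) int, pseudo-label counts of previous batch
    initialized: bool = False

    @classmethod
    def zeros(cls, n_classes: int, d_f: int) -> "CentroidState":
        return cls(memory=np.zeros((n_classes, d_f), dtype=np.float64),
                   counts=np.zeros(n_classes, dtype=np.int64),
                   initialized=False)

    @property
    def n_classes(self) -> int:
        return self.memory.shape[0]

    @property
    def update_rates(self) -> np.ndarray:
        """eta_k = exp(-t_k), in (0, 1]."""
        return np.exp(-self.counts.astype(np.float64))

    def with_counts(self, counts: np.ndarray) -> "CentroidState":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (self.n_classes,) or (counts < 0).any():
            raise ValueError(f"counts must be {self.n_classes} non-negative integers")
        return replace(self, counts=counts)


def soft_weighted_centroids(features: np.ndarray, probs: np.ndarray,
                            memory: np.ndarray | None = None,
                            eps: float = EMPTY_CLASS_EPS):
    """Probability-weighted class centroids of a feature batch.

    Returns ``(centroids, valid)`` where ``valid[k]`` is False for classes
    whose total weight falls below ``eps``; such rows are backfilled from
    ``memory`` when given (zeros otherwise) and should be excluded from the
    global-consistency loss.
    """
    feats = np.asarray(features, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] == 0:
        raise ValueError(f"features must be a non-empty (n, d_f) matrix, got {feats.shape}")
    if p.ndim != 2 or p.shape[0] != feats.shape[0]:
        raise ValueError(
            f"probs shape {p.shape} incompatible with features shape {feats.shape}")

    weight = p.sum(axis=0)                        # (N_c,)
    valid = weight >= eps
    centroids = np.zeros((p.shape[1], feats.shape[1]), dtype=np.float64)
    if valid.any():
        centroids[valid] = (p[:, valid].T @ feats) / weight[valid, None]
    if memory is not None and (~valid).any():
        centroids[~valid] = np.asarray(memory, dtype=np.float64)[~valid]
    return centroids, valid


def assign_pseudolabels(features: np.ndarray, centroids: np.ndarray,
                        valid: np.ndarray | None = None) -> np.ndarray:
    """Nearest-centroid labels, Euclidean metric, ties to the smallest index."""
    feats = np.asarray(features, dtype=np.float64)
    cents = np.asarray(centroids, dtype=np.float64)
    if valid is None:
        valid = np.ones(len(cents), dtype=bool)
    if not np.isfinite(cents[valid]).all():
        raise ValueError("non-finite centroid row that is not flagged empty")
    safe = np.where(valid[:, None], cents, 0.0)  # invalid rows masked below
    # squared distances via expansion; double precision keeps argmin ties exact
    d2 = (np.einsum("ij,ij->i", feats, feats)[:, None]
          - 2.0 * feats @ safe.T
          + np.einsum("kj,kj->k", safe, safe)[None, :])
    d2[:, ~valid] = np.inf
    return np.argmin(d2, axis=1)


def update_memory(state: CentroidState, local_centroids: np.ndarray,
                  batch_class_counts: np.ndarray | None = None,
                  valid: np.ndarray | None = None) -> CentroidState:
    """Damped memory update M_k <- (1 - eta) M_k + eta c_k, eta = exp(-t_k).

    ``t_k`` comes from ``state.counts`` (the previous batch); afterwards the
    counts are replaced by ``batch_class_counts`` (pass None to set them
    later with :meth:`CentroidState.with_counts`, e.g. when the current
    batch's pseudo-labels are assigned against the updated memory). Classes
    flagged empty (``valid[k]`` False) keep their memory row. On the first
    ever update the memory is seeded directly from the local centroids,
    which coincides with the t_k = 0, eta = 1 full replacement.
    """
    local = np.asarray(local_centroids, dtype=np.float64)
    if local.shape != state.memory.shape:
        raise ValueError(
            f"local centroids shape {local.shape} != memory shape {state.memory.shape}")
    if valid is None:
        valid = np.ones(state.n_classes, dtype=bool)
    if batch_class_counts is not None:
        batch_class_counts = np.asarray(batch_class_counts, dtype=np.int64)
        if (batch_class_counts < 0).any():
            raise ValueError("batch_class_counts must be non-negative")

    eta = state.update_rates[:, None]
    if state.initialized:
        new_mem = np.where(valid[:, None], (1.0 - eta) * state.memory + eta * local,
                           state.memory)
    else:
        new_mem = np.where(valid[:, None], local, state.memory)
    if not np.isfinite(new_mem).all():
        raise FloatingPointError("centroid memory became non-finite")
    counts = state.counts if batch_class_counts is None else batch_class_counts
    return CentroidState(memory=new_mem, counts=np.asarray(counts, dtype=np.int64),
                         initialized=True)


def confidence_pseudolabels(probs: np.ndarray, threshold: float):
    """Argmax pseudo-labels kept only above a confidence threshold.

    The ablation baseline used when the weight clustering unit is disabled:
    returns ``(labels, keep)`` with ``keep[j]`` True iff
    ``max_k probs[j, k] >= threshold``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError(f"probs must be an (n, N_c) matrix, got shape {p.shape}")
    labels = np.argmax(p, axis=1)
    keep = p.max(axis=1) >= threshold
    return labels, keep
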