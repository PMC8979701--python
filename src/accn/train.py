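"""ACCN training loop: Model / Results objects and the ablation harness.

:class:`ACCNModel` holds the data and configuration; :meth:`ACCNModel.fit`
runs the semi-supervised loop and returns :class:`ACCNResults` carrying the
trained network, the centroid memory, the per-step loss history and
evaluation helpers.

Per optimizer step the loop
(1) forwards the labeled sub-batch with its weak views and takes the
    labeled cross-entropy;
(2) forwards the raw unlabeled sub-batch (anchors) and its K strong views
    and takes the augmentation-consistency loss against the anchors;
(3) computes soft-weighted batch centroids, measures the global-consistency
    loss against the centroid memory, then applies the damped memory
    update;
(4) pseudo-labels the batch by nearest (memory) centroid and takes the
    pseudo-cross-entropy over raw + strong views;
(5) steps the optimizer on the gamma-weighted total.

Pseudo-label and anchor targets are constants; gradients reach the
centroids only through the features. The clustering losses switch on after
a short supervised warm-up, since an untrained classifier's soft weights
are near-uniform and the weighted centroids all collapse to the global
feature mean. One root seed fans out to initialization, batching and
augmentation streams, and the whole trajectory is reproducible bit-for-bit
(checkpoints capture optimizer, memory, batcher and RNG state, so a
save/resume run retraces an uninterrupted one).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import objectives
from .augment import AugmentationPolicy, StrongPolicy, WeakPolicy, strong_augment, weak_augment
from .clustering import CentroidState, assign_pseudolabels, confidence_pseudolabels, \
    soft_weighted_centroids, update_memory
from .evaluation import EvalReport, evaluate_probabilities
from .network import Network, build_network, softmax
from .nn import SGD, Adam
from .synthetic import make_benchmark

__all__ = ["TrainConfig", "ACCNModel", "ACCNResults", "TrainingDiverged",
           "run_ablation", "ablation_table", "benchmark_protocol",
           "ABLATION_VARIANTS"]

HISTORY_COLUMNS = ("epoch", "step", "l_lce", "l_ac", "l_gc", "l_pce", "total")


class TrainingDiverged(RuntimeError):
    """Raised when a loss turns NaN/Inf; carries a diagnostic batch dump."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"                  # 'adam' | 'sgd' (momentum 0.9)
    gammas: tuple[float, float, float] = objectives.DEFAULT_GAMMAS
    warmup_epochs: int = 1                   # supervised epochs before gc/pce
    backbone: str = "tiny_cnn"
    widths: tuple[int, int, int] = (16, 32, 64)
    n_classes: int = 2
    in_channels: int = 3
    l2_normalize_features: bool = False
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    ac_norm: str = "l2sq"
    assign_from_memory: bool = True          # pseudo-labels vs memory (else local)
    pseudolabel_refresh: str = "batch"       # 'batch': re-assign every step;
                                             # 'epoch': freeze pce targets between
                                             # full-pool refreshes (pair with a
                                             # longer warm-up)
    epoch_refresh: bool = True               # full-pool centroid refresh at epoch end
    disable_acl: bool = False                # ablation: drop strong views + L_ac
    disable_wcu: bool = False                # ablation: confidence pseudo-labels, no L_gc
    confidence_threshold: float = 0.95
    steps_per_epoch: int | None = None
    restore_best: bool = False               # restore best-val-accuracy weights at end
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 2:
            raise ValueError(f"batch_size must be >= 2, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")
        if any(g < 0 for g in self.gammas):
            raise ValueError(f"gammas must be non-negative, got {self.gammas}")
        if self.warmup_epochs < 0:
            raise ValueError(f"warmup_epochs must be >= 0, got {self.warmup_epochs}")
        if not (0.0 < self.confidence_threshold < 1.0):
            raise ValueError(
                f"confidence_threshold must be in (0, 1), got {self.confidence_threshold}")
        if self.pseudolabel_refresh not in ("epoch", "batch"):
            raise ValueError(f"pseudolabel_refresh must be 'epoch' or 'batch', "
                             f"got {self.pseudolabel_refresh!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "policy"}
        d["gammas"] = list(self.gammas)
        d["widths"] = list(self.widths)
        p = self.policy
        d["policy"] = {
            "weak": {"crop_area": list(p.weak.crop_area), "flip_prob": p.weak.flip_prob},
            "strong": {"n_ops": p.strong.n_ops, "magnitude": p.strong.magnitude,
                       "fixed_sequence": list(p.strong.fixed_sequence),
                       "cutout_fraction": p.strong.cutout_fraction},
            "K": p.K,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        p = d.pop("policy", None)
        policy = AugmentationPolicy() if p is None else AugmentationPolicy(
            weak=WeakPolicy(crop_area=tuple(p["weak"]["crop_area"]),
                            flip_prob=p["weak"]["flip_prob"]),
            strong=StrongPolicy(n_ops=p["strong"]["n_ops"],
                                magnitude=p["strong"]["magnitude"],
                                fixed_sequence=tuple(p["strong"]["fixed_sequence"]),
                                cutout_fraction=p["strong"]["cutout_fraction"]),
            K=p["K"])
        d["gammas"] = tuple(d.get("gammas", objectives.DEFAULT_GAMMAS))
        d["widths"] = tuple(d.get("widths", (16, 32, 64)))
        if d.get("steps_per_epoch") is not None:
            d["steps_per_epoch"] = int(d["steps_per_epoch"])
        return cls(policy=policy, **d)


class _Batcher:
    """Deterministic shuffled cycling over indices; state save/restore."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self._perm = np.empty(0, dtype=np.intp)
        self._pos = 0

    def next(self, size: int) -> np.ndarray:
        out = np.empty(size, dtype=np.intp)
        got = 0
        while got < size:
            if self._pos >= len(self._perm):
                self._perm = self.rng.permutation(self.n)
                self._pos = 0
            take = min(size - got, len(self._perm) - self._pos)
            out[got:got + take] = self._perm[self._pos:self._pos + take]
            self._pos += take
            got += take
        return out

    def state_dict(self) -> dict:
        return {"perm": self._perm.tolist(), "pos": self._pos,
                "rng": self.rng.bit_generator.state}

    def load_state_dict(self, state: dict) -> None:
        self._perm = np.asarray(state["perm"], dtype=np.intp)
        self._pos = int(state["pos"])
        self.rng.bit_generator.state = state["rng"]


def _as_float_images(images, name: str) -> np.ndarray:
    x = np.asarray(images)
    if x.ndim != 4:
        raise ValueError(f"{name} must be a (N, H, W, C) array, got shape {x.shape}")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return np.ascontiguousarray(x, dtype=np.float32)


class ACCNModel:
    """Semi-supervised classifier trained with augmentation consistency and
    weight clustering.

    Parameters
    ----------
    labeled_images, labeled_labels
        The annotated set; at least one sample of every class.
    unlabeled_images
        The unlabeled pool (may be None/empty: training degenerates to the
        plain supervised cross-entropy loop).
    config
        :class:`TrainConfig`; ``config.seed`` drives every random stream.
    val_images, val_labels
        Optional held-out data evaluated at each epoch end.
    """

    def __init__(self, labeled_images, labeled_labels, unlabeled_images=None,
                 config: TrainConfig | None = None,
                 val_images=None, val_labels=None):
        self.config = config or TrainConfig()
        self.labeled_images = _as_float_images(labeled_images, "labeled_images")
        self.labeled_labels = np.asarray(labeled_labels, dtype=np.intp)
        if len(self.labeled_images) == 0:
            raise ValueError("labeled set is empty; training requires labels")
        if len(self.labeled_images) != len(self.labeled_labels):
            raise ValueError("labeled_images and labeled_labels length mismatch")
        present = np.unique(self.labeled_labels)
        expected = np.arange(self.config.n_classes)
        missing = np.setdiff1d(expected, present)
        if missing.size:
            raise ValueError(f"no labeled sample for class(es) {missing.tolist()}")
        if unlabeled_images is None or len(unlabeled_images) == 0:
            self.unlabeled_images = None
        else:
            self.unlabeled_images = _as_float_images(unlabeled_images, "unlabeled_images")
        self.val_images = None if val_images is None else _as_float_images(val_images, "val_images")
        self.val_labels = None if val_labels is None else np.asarray(val_labels, dtype=np.intp)

    @classmethod
    def from_datasets(cls, labeled, unlabeled=None, config=None, test=None):
        """Build from :mod:`accn.synthetic` set objects (or anything with
        ``.images``/``.labels``)."""
        return cls(labeled.images, labeled.labels,
                   None if unlabeled is None else unlabeled.images,
                   config=config,
                   val_images=None if test is None else test.images,
                   val_labels=None if test is None else test.labels)

    # ------------------------------------------------------------------

    def _steps_per_epoch(self) -> int:
        if self.config.steps_per_epoch is not None:
            return int(self.config.steps_per_epoch)
        n = (len(self.unlabeled_images) if self.unlabeled_images is not None
             else len(self.labeled_images))
        return max(1, math.ceil(n / self.config.batch_size))

    def fit(self, resume_from=None) -> "ACCNResults":
        cfg = self.config
        # root seed fans out: [0] init, [1] labeled batching, [2] unlabeled
        # batching, [3] augmentation
        seeds = np.random.SeedSequence(cfg.seed).spawn(4)
        rng_init = np.random.default_rng(seeds[0])
        net = build_network(backbone=cfg.backbone, n_classes=cfg.n_classes,
                            in_channels=cfg.in_channels, widths=cfg.widths,
                            l2_normalize_features=cfg.l2_normalize_features,
                            seed=rng_init)
        params = net.params()
        opt = (Adam(params, lr=cfg.learning_rate) if cfg.optimizer == "adam"
               else SGD(params, lr=cfg.learning_rate))
        lab_batcher = _Batcher(len(self.labeled_images), np.random.default_rng(seeds[1]))
        unl_batcher = (None if self.unlabeled_images is None
                       else _Batcher(len(self.unlabeled_images), np.random.default_rng(seeds[2])))
        rng_aug = np.random.default_rng(seeds[3])
        state = CentroidState.zeros(cfg.n_classes, net.d_f)
        history: list[tuple] = []
        epoch_rows: list[dict] = []
        best = {"val_acc": -np.inf, "epoch": None, "params": None}
        start_epoch = 0
        self._pool_plabels = None

        if resume_from is not None:
            start_epoch, state, history, epoch_rows, best, self._pool_plabels = \
                _load_checkpoint(resume_from, net, opt, lab_batcher, unl_batcher, rng_aug)

        steps = self._steps_per_epoch()
        for epoch in range(start_epoch, cfg.epochs):
            clustering_on = epoch >= cfg.warmup_epochs
            for step in range(steps):
                row = self._train_step(net, opt, state, lab_batcher, unl_batcher,
                                       rng_aug, clustering_on, epoch, step)
                state = row.pop("state")
                history.append(tuple(row[c] for c in HISTORY_COLUMNS))
            state = self._epoch_end(net, state, epoch)
            erow = self._epoch_eval(net, history, steps, epoch)
            epoch_rows.append(erow)
            if erow.get("val_acc") is not None and erow["val_acc"] > best["val_acc"]:
                best = {"val_acc": erow["val_acc"], "epoch": epoch + 1,
                        "params": [p.value.copy() for p in params]}

        if cfg.restore_best and best["params"] is not None:
            for p, v in zip(params, best["params"]):
                p.value[...] = v

        pseudo = self._final_pseudolabels(net, state)
        return ACCNResults(
            network=net, centroid_state=state,
            history=pd.DataFrame(history, columns=HISTORY_COLUMNS),
            epoch_history=pd.DataFrame(epoch_rows),
            config=cfg, pseudo_labels_=pseudo[0], pseudo_label_mask_=pseudo[1],
            best_epoch=best["epoch"],
            best_val_acc=None if best["epoch"] is None else best["val_acc"],
            _opt=opt, _batchers=(lab_batcher, unl_batcher), _rng_aug=rng_aug,
            _pool_plabels=self._pool_plabels)

    # ------------------------------------------------------------------

    def _train_step(self, net, opt, state, lab_batcher, unl_batcher, rng_aug,
                    clustering_on, epoch, step):
        cfg = self.config
        g1, g2, g3 = cfg.gammas
        B = cfg.batch_size

        li = lab_batcher.next(B)
        xl_raw = self.labeled_images[li]
        yl = self.labeled_labels[li]
        if cfg.disable_acl:
            x_l, y_l = xl_raw, yl
        else:
            weak = np.stack([weak_augment(im, cfg.policy, rng_aug) for im in xl_raw])
            x_l = np.concatenate([xl_raw, weak])
            y_l = np.concatenate([yl, yl])
        logits_l, _, cache_l = net.forward(x_l)
        l_lce, dlog_l = objectives.ce_from_logits(logits_l, y_l)

        l_ac = l_gc = l_pce = 0.0
        ui = None
        cache_u = cache_s = None
        dlog_u = dlog_s = dfeat_u = None
        use_strong = (self.unlabeled_images is not None and not cfg.disable_acl
                      and (g1 > 0 or g3 > 0))

        if self.unlabeled_images is not None:
            ui = unl_batcher.next(B)
            xu = self.unlabeled_images[ui]
            logits_u, feats_u, cache_u = net.forward(xu)
            probs_u = softmax(logits_u)  # anchors: constants below

            logits_s = None
            if use_strong:
                views = []
                for im in xu:
                    views.extend(strong_augment(im, cfg.policy, rng_aug))
                xs = np.stack(views)
                pair_index = np.repeat(np.arange(B), cfg.policy.K)
                logits_s, _, cache_s = net.forward(xs)
                l_ac, dlog_s = objectives.ac_grad_from_logits(
                    logits_s, probs_u, pair_index, norm=cfg.ac_norm)
                dlog_s = g1 * dlog_s

            if clustering_on:
                if cfg.disable_wcu:
                    plabels, keep = confidence_pseudolabels(
                        probs_u, cfg.confidence_threshold)
                else:
                    local, valid = soft_weighted_centroids(
                        feats_u, probs_u,
                        memory=state.memory if state.initialized else None)
                    if state.initialized:
                        l_gc = objectives.gc_loss(state.memory, local, valid)
                        dfeat_u = g2 * objectives.gc_feature_grad(
                            feats_u, probs_u, local, state.memory, valid)
                    state = update_memory(state, local, None, valid)
                    if (cfg.pseudolabel_refresh == "epoch"
                            and self._pool_plabels is not None):
                        plabels = self._pool_plabels[ui]
                    else:
                        ref = state.memory if cfg.assign_from_memory else local
                        plabels = assign_pseudolabels(feats_u, ref)
                    state = state.with_counts(
                        np.bincount(plabels, minlength=cfg.n_classes))
                    keep = np.ones(B, dtype=bool)

                if g3 > 0 and keep.any():
                    l_pce, dlog_u, dlog_s = self._pce(
                        logits_u, logits_s, plabels, keep, cfg, g3, dlog_s)

        total = objectives.total_loss(l_lce, l_ac, l_gc, l_pce, cfg.gammas)
        if not np.isfinite(total):
            diag = {"epoch": epoch + 1, "step": step + 1,
                    "l_lce": l_lce, "l_ac": l_ac, "l_gc": l_gc, "l_pce": l_pce,
                    "labeled_indices": li.tolist(),
                    "unlabeled_indices": None if ui is None else ui.tolist()}
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch + 1} step {step + 1}: "
                f"lce={l_lce} ac={l_ac} gc={l_gc} pce={l_pce}", diag)

        opt.zero_grad()
        net.backward(cache_l, dlogits=dlog_l)
        if cache_s is not None and dlog_s is not None:
            net.backward(cache_s, dlogits=dlog_s)
        if cache_u is not None and (dlog_u is not None or dfeat_u is not None):
            net.backward(cache_u, dlogits=dlog_u, dfeatures=dfeat_u)
        opt.step()

        return {"epoch": epoch + 1, "step": step + 1, "l_lce": l_lce,
                "l_ac": l_ac, "l_gc": l_gc, "l_pce": l_pce, "total": total,
                "state": state}

    @staticmethod
    def _pce(logits_u, logits_s, plabels, keep, cfg, g3, dlog_s):
        """Pseudo-CE over kept raw rows and their strong views (one mean)."""
        K = cfg.policy.K
        rows = [logits_u[keep]]
        targets = [plabels[keep]]
        if logits_s is not None:
            keep_s = np.repeat(keep, K)
            rows.append(logits_s[keep_s])
            targets.append(np.repeat(plabels, K)[keep_s])
        logits_all = np.concatenate(rows)
        l_pce, dall = objectives.ce_from_logits(logits_all, np.concatenate(targets))
        n_u = int(keep.sum())
        dlog_u = np.zeros_like(logits_u, dtype=np.float64)
        dlog_u[keep] = g3 * dall[:n_u]
        if logits_s is not None:
            ds = np.zeros_like(logits_s, dtype=np.float64)
            ds[np.repeat(keep, K)] = g3 * dall[n_u:]
            dlog_s = ds if dlog_s is None else dlog_s + ds
        return l_pce, dlog_u, dlog_s

    def _pool_pass(self, net, batch: int = 128):
        feats, probs = [], []
        x = self.unlabeled_images
        for i in range(0, len(x), batch):
            lo, f, _ = net.forward(x[i:i + batch])
            feats.append(f)
            probs.append(softmax(lo))
        return np.concatenate(feats), np.concatenate(probs)

    def _epoch_end(self, net, state, epoch):
        """Full-pool centroid refresh (and pseudo-label freeze) at epoch end.

        Runs from the end of the last warm-up epoch onward so that frozen
        targets exist before the first clustering epoch begins.
        """
        cfg = self.config
        due = (epoch + 1) >= cfg.warmup_epochs
        want = cfg.epoch_refresh or cfg.pseudolabel_refresh == "epoch"
        if (due and want and not cfg.disable_wcu
                and self.unlabeled_images is not None):
            feats, probs = self._pool_pass(net)
            local, valid = soft_weighted_centroids(
                feats, probs, memory=state.memory if state.initialized else None)
            state = update_memory(state, local, None, valid)
            if cfg.pseudolabel_refresh == "epoch":
                ref = state.memory if cfg.assign_from_memory else local
                labels = assign_pseudolabels(feats, ref)
                # freeze only a non-degenerate assignment: an all-one-class
                # labelling would turn the pce into a collapse engine
                if len(np.unique(labels)) == cfg.n_classes:
                    self._pool_plabels = labels
        return state

    def _epoch_eval(self, net, history, steps, epoch):
        recent = history[-steps:]
        cols = dict(zip(HISTORY_COLUMNS, zip(*recent)))
        row = {"epoch": epoch + 1,
               **{f"mean_{k}": float(np.mean(cols[k]))
                  for k in ("l_lce", "l_ac", "l_gc", "l_pce", "total")},
               "val_acc": None, "val_auc": None}
        if self.val_images is not None:
            rep = evaluate_probabilities(net.predict(self.val_images), self.val_labels)
            row["val_acc"], row["val_auc"] = rep.acc, rep.auc
        return row

    def _final_pseudolabels(self, net, state):
        """One fresh full-pool clustering pass under the final network.

        Recomputing the centroids here keeps the assignment consistent with
        the network actually returned (relevant when best-epoch weights were
        restored and the memory would otherwise be stale).
        """
        if self.unlabeled_images is None:
            return None, None
        feats, probs = self._pool_pass(net)
        if self.config.disable_wcu:
            labels, keep = confidence_pseudolabels(probs, self.config.confidence_threshold)
            return labels, keep
        if not state.initialized:
            return None, None
        local, valid = soft_weighted_centroids(feats, probs, memory=state.memory)
        labels = assign_pseudolabels(feats, local, valid)
        return labels, np.ones(len(labels), dtype=bool)


@dataclass
class ACCNResults:
    """Outcome of :meth:`ACCNModel.fit`.

    ``history`` has one row per optimizer step with the four loss terms and
    the total; ``epoch_history`` aggregates per epoch and holds validation
    metrics. ``pseudo_labels_`` is the final nearest-centroid assignment of
    the unlabeled pool (None when there was none).
    """

    network: Network
    centroid_state: CentroidState
    history: pd.DataFrame
    epoch_history: pd.DataFrame
    config: TrainConfig
    pseudo_labels_: np.ndarray | None
    pseudo_label_mask_: np.ndarray | None
    best_epoch: int | None
    best_val_acc: float | None
    _opt: object = None
    _batchers: tuple = None
    _rng_aug: object = None
    _pool_plabels: object = None

    # -- inference ------------------------------------------------------

    def predict(self, images) -> np.ndarray:
        return self.network.predict(_as_float_images(images, "images"))

    def predict_labels(self, images) -> np.ndarray:
        return np.argmax(self.predict(images), axis=1)

    def assign_pseudolabels(self, images) -> np.ndarray:
        """Nearest-memory-centroid labels for arbitrary images."""
        if not self.centroid_state.initialized:
            raise RuntimeError("centroid memory was never initialized "
                               "(no unlabeled data or clustering disabled)")
        feats = self.network.extract_features(_as_float_images(images, "images"))
        return assign_pseudolabels(feats, self.centroid_state.memory)

    def evaluate(self, images, labels, positive_class: int = 1) -> EvalReport:
        return evaluate_probabilities(self.predict(images), labels,
                                      positive_class=positive_class)

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        h = self.history
        cfg = self.config
        lines = [
            "ACCN training results",
            "=" * 52,
            f"backbone            {cfg.backbone} (d_f={self.network.d_f})",
            f"classes             {cfg.n_classes}",
            f"epochs x steps      {h['epoch'].max()} x {h[h.epoch == 1].shape[0]}",
            f"optimizer           {cfg.optimizer} (lr={cfg.learning_rate})",
            f"gammas (ac, gc, pce) {cfg.gammas}",
            "-" * 52,
            "final-epoch mean losses:",
        ]
        last = h[h.epoch == h.epoch.max()]
        for c in ("l_lce", "l_ac", "l_gc", "l_pce", "total"):
            lines.append(f"  {c:<8} {last[c].mean():.4f}")
        if self.best_epoch is not None:
            lines.append(f"best val accuracy   {self.best_val_acc:.3f} "
                         f"(epoch {self.best_epoch})")
        return "\n".join(lines)

    # -- checkpointing --------------------------------------------------

    def save_checkpoint(self, path) -> None:
        _save_checkpoint(path, self)


def _save_checkpoint(path, res: ACCNResults) -> None:
    net, opt = res.network, res._opt
    lab_b, unl_b = res._batchers
    arrays = {f"param_{i}": p.value for i, p in enumerate(net.params())}
    ostate = opt.state_dict()
    for i, a in enumerate(ostate["m"]):
        arrays[f"opt_m_{i}"] = a
    for i, a in enumerate(ostate["v"]):
        arrays[f"opt_v_{i}"] = a
    arrays["memory"] = res.centroid_state.memory
    arrays["mem_counts"] = res.centroid_state.counts
    for col in HISTORY_COLUMNS:
        arrays[f"hist_{col}"] = res.history[col].to_numpy()
    meta = {
        "opt_t": int(ostate["t"]),
        "mem_initialized": bool(res.centroid_state.initialized),
        "epoch_done": int(res.history["epoch"].max()) if len(res.history) else 0,
        "train_config": res.config.to_dict(),
        "lab_batcher": lab_b.state_dict(),
        "unl_batcher": None if unl_b is None else unl_b.state_dict(),
        "rng_aug": res._rng_aug.bit_generator.state,
        "epoch_rows": res.epoch_history.to_dict(orient="records"),
        "best": {"epoch": res.best_epoch, "val_acc": res.best_val_acc},
        "pool_plabels": (None if res._pool_plabels is None
                         else res._pool_plabels.tolist()),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint_config(path) -> TrainConfig:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
    return TrainConfig.from_dict(meta["train_config"])


def _load_checkpoint(path, net, opt, lab_batcher, unl_batcher, rng_aug):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"param_{i}"]
        ostate = {"t": meta["opt_t"],
                  "m": [data[f"opt_m_{i}"] for i in range(len(net.params()))
                        if f"opt_m_{i}" in data],
                  "v": [data[f"opt_v_{i}"] for i in range(len(net.params()))
                        if f"opt_v_{i}" in data]}
        opt.load_state_dict(ostate)
        state = CentroidState(memory=data["memory"].astype(np.float64),
                              counts=data["mem_counts"].astype(np.int64),
                              initialized=meta["mem_initialized"])
        history = list(zip(*[data[f"hist_{c}"].tolist() for c in HISTORY_COLUMNS]))
    lab_batcher.load_state_dict(meta["lab_batcher"])
    if unl_batcher is not None and meta["unl_batcher"] is not None:
        unl_batcher.load_state_dict(meta["unl_batcher"])
    rng_aug.bit_generator.state = meta["rng_aug"]
    best_meta = meta["best"]
    best = {"val_acc": (-np.inf if best_meta["val_acc"] is None else best_meta["val_acc"]),
            "epoch": best_meta["epoch"], "params": None}
    pool = meta.get("pool_plabels")
    pool = None if pool is None else np.asarray(pool, dtype=np.intp)
    return meta["epoch_done"], state, history, meta["epoch_rows"], best, pool


# ---------------------------------------------------------------------------
# Ablation harness

ABLATION_VARIANTS = ("full", "supervised", "no_acl", "no_wcu",
                     "label_budget", "positive_fraction")

_VAL_SEED_OFFSET = 770_001  # validation draw independent of train/test draws


def benchmark_protocol(seed: int, epochs: int = 30, **overrides) -> TrainConfig:
    """The canonical training protocol of the synthetic benchmark.

    A 10-epoch supervised warm-up operationalizes training the clustering
    unit from an annotated-data baseline network; pseudo-label targets are
    frozen between full-pool refreshes at epoch boundaries; the returned
    model is the best epoch by held-out validation accuracy. The optimizer
    step budget is matched across variants (one unlabeled-pool pass per
    epoch) so that labeled-only baselines are trained to convergence rather
    than starved of steps.
    """
    defaults = dict(epochs=epochs, warmup_epochs=10, pseudolabel_refresh="epoch",
                    restore_best=True, seed=seed)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def _benchmark_val(seed: int, bench: dict):
    from .synthetic import SyntheticSpec, generate_dataset
    spec = SyntheticSpec(
        n_classes=bench.get("n_classes", 2),
        n_labeled_per_class=50, n_unlabeled_per_class=0,
        image_size=bench.get("image_size", 32),
        separation=bench.get("separation", 6.0),
        noise_sd=bench.get("noise_sd", 0.1),
        seed=seed + _VAL_SEED_OFFSET)
    val, _ = generate_dataset(spec)
    return val


def run_ablation(which: str, *, seed: int = 0, value=None,
                 config: TrainConfig | None = None,
                 benchmark_kwargs: dict | None = None,
                 positive_class: int = 1, return_results: bool = False):
    """Train one ablation variant on the synthetic benchmark; return metrics.

    Variants: ``full`` (the complete method), ``supervised`` (labeled data
    only, all gammas 0), ``no_acl`` (raw images only, augmentation
    consistency dropped), ``no_wcu`` (clustering replaced by
    confidence-threshold pseudo-labels, global consistency dropped),
    ``label_budget`` (``value`` = total labeled images) and
    ``positive_fraction`` (``value`` = fraction of positives in the
    unlabeled pool). All variants share the benchmark protocol: matched
    step budget, best-epoch selection on a common validation draw.
    """
    if which not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {which!r}; "
                         f"choose from {ABLATION_VARIANTS}")
    cfg = config or benchmark_protocol(seed)
    bench = dict(benchmark_kwargs or {})
    if which == "label_budget":
        if value is None or int(value) < cfg.n_classes:
            raise ValueError("label_budget needs value >= n_classes (total labeled)")
        bench["n_labeled_per_class"] = int(value) // cfg.n_classes
    if which == "positive_fraction":
        if value is None:
            raise ValueError("positive_fraction needs a value in [0, 1]")
        bench["positive_fraction_unlabeled"] = float(value)
    labeled, unlabeled, test = make_benchmark(seed, **bench)
    val = _benchmark_val(seed, bench)

    cfg = replace(cfg, seed=seed)
    if cfg.steps_per_epoch is None:
        # matched optimizer-step budget across variants, incl. supervised
        cfg = replace(cfg, steps_per_epoch=max(
            1, math.ceil(len(unlabeled.images) / cfg.batch_size)))
    unl = unlabeled.images
    if which == "supervised":
        cfg = replace(cfg, gammas=(0.0, 0.0, 0.0))
        unl = None
    elif which == "no_acl":
        cfg = replace(cfg, disable_acl=True)
    elif which == "no_wcu":
        cfg = replace(cfg, disable_wcu=True)

    res = ACCNModel(labeled.images, labeled.labels, unl, config=cfg,
                    val_images=val.images, val_labels=val.labels).fit()
    rep = res.evaluate(test.images, test.labels, positive_class=positive_class)
    row = {"variant": which if value is None else f"{which}={value}",
           "seed": seed, "ACC": rep.acc, "SEN": rep.sen, "SPE": rep.spe,
           "AUC": rep.auc}
    if return_results:
        return row, res, (labeled, unlabeled, test)
    return row


def ablation_table(variants, seeds=(0,), *, config: TrainConfig | None = None,
                   benchmark_kwargs: dict | None = None,
                   out_csv=None) -> pd.DataFrame:
    """Run several (variant, seed) ablations; rows of (variant, ACC, SEN, SPE, AUC)."""
    rows = []
    for v in variants:
        which, _, val = v.partition("=")
        value = float(val) if val else None
        for s in seeds:
            rows.append(run_ablation(which, seed=int(s), value=value,
                                     config=config, benchmark_kwargs=benchmark_kwargs))
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
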