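"""Feature extractor G + linear classifier F.

The network computes ``P(x) = softmax(F(G(x)))``: G maps an image batch to
d_f-dimensional feature vectors (global average pooled), F is a single
linear map to class scores. Losses work on the raw logits (log-softmax is
taken where needed); :meth:`Network.predict` returns probabilities.

Features used by the clustering unit are the G outputs, un-normalized by
default (``l2_normalize_features`` switches this on).
"""

from __future__ import annotations

import json

import numpy as np

from . import nn

__all__ = ["Network", "build_network", "softmax", "log_softmax",
           "extract_features", "predict"]


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


class Network:
    """Backbone-agnostic classifier: ``logits = F(G(x))``."""

    def __init__(self, backbone: nn.Sequential, head: nn.Linear, *,
                 n_classes: int, d_f: int, config: dict):
        self.backbone = backbone
        self.head = head
        self.n_classes = n_classes
        self.d_f = d_f
        self.config = dict(config)
        self.l2_normalize_features = bool(config.get("l2_normalize_features", False))

    # -- core passes -------------------------------------------------------

    def params(self) -> list[nn.Param]:
        return self.backbone.params() + self.head.params()

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim != 4:
            raise ValueError(f"expected a (N, H, W, C) batch, got shape {x.shape}")
        c_exp = self.config.get("in_channels", 3)
        if x.shape[3] != c_exp:
            raise ValueError(
                f"channel mismatch: expected {c_exp} channels, got {x.shape[3]}")
        if x.shape[1] < 8 or x.shape[2] < 8:
            raise ValueError(
                f"input too small: expected at least 8x8 pixels, got "
                f"{x.shape[1]}x{x.shape[2]}")
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        return np.ascontiguousarray(x, dtype=np.float32)

    def forward(self, images: np.ndarray):
        """Full differentiable pass. Returns (logits, features, cache)."""
        # center [0,1] pixels so first-layer activations are ~zero-mean
        x = self._check_input(images) - np.float32(0.5)
        feats, bcache = self.backbone.forward(x)
        norms = None
        if self.l2_normalize_features:
            norms = np.linalg.norm(feats, axis=1, keepdims=True) + 1e-12
            feats = feats / norms
        logits, hcache = self.head.forward(feats)
        return logits, feats, (bcache, hcache, norms, feats)

    def backward(self, cache, dlogits=None, dfeatures=None) -> None:
        """Accumulate parameter gradients from logit and/or feature grads."""
        bcache, hcache, norms, feats = cache
        dfeat = None
        if dlogits is not None:
            dfeat = self.head.backward(dlogits.astype(np.float32), hcache)
        if dfeatures is not None:
            df = dfeatures.astype(np.float32)
            dfeat = df if dfeat is None else dfeat + df
        if dfeat is None:
            return
        if norms is not None:
            # d(f/|f|) backprop: (I - ffᵀ)/|f| applied row-wise
            dfeat = (dfeat - feats * (dfeat * feats).sum(axis=1, keepdims=True)) / norms
        self.backbone.backward(dfeat, bcache)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- inference helpers -------------------------------------------------

    def extract_features(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._check_input(images)
        out = [self.forward(x[i:i + batch_size])[1]
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.d_f), np.float32)

    def predict_logits(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._check_input(images)
        out = [self.forward(x[i:i + batch_size])[0]
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.n_classes), np.float32)

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class-probability rows (each on the simplex)."""
        return softmax(self.predict_logits(images, batch_size))

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            config = json.loads(bytes(data["config_json"]).decode())
            net = build_network(**{k: config[k] for k in
                                   ("backbone", "n_classes", "in_channels",
                                    "widths", "l2_normalize_features")},
                                seed=0)
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"param_{i}"]
        return net


def build_network(backbone: str = "tiny_cnn", n_classes: int = 2,
                  in_channels: int = 3, widths=(16, 32, 64),
                  l2_normalize_features: bool = False,
                  seed: int | np.random.Generator = 0) -> Network:
    """Construct a randomly initialized Network.

    ``seed`` may be an integer or an already fanned-out Generator so the
    trainer can keep one root seed for everything.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bb, d_f = nn.build_backbone(backbone, in_channels, widths, rng)
    head = nn.Linear(d_f, n_classes, rng)
    config = {"backbone": backbone, "n_classes": n_classes,
              "in_channels": in_channels, "widths": list(widths),
              "l2_normalize_features": l2_normalize_features, "d_f": d_f}
    return Network(bb, head, n_classes=n_classes, d_f=d_f, config=config)


def extract_features(images: np.ndarray, net: Network) -> np.ndarray:
    """One d_f-vector per image (functional form of Network.extract_features)."""
    return net.extract_features(images)


def predict(images: np.ndarray, net: Network) -> np.ndarray:
    """Probability rows P(x) = softmax(F(G(x)))."""
    return net.predict(images)
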