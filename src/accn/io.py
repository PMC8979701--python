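"""Dataset reading: CSV manifests + image files -> in-memory sets.

A manifest is a CSV with columns ``filename,label`` where the label is an
integer class index for annotated rows and ``-1`` for unlabeled rows.
Images are loaded as RGB, optionally resized, and scaled to [0, 1].
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .synthetic import LabeledSet, UnlabeledSet, UNLABELED_TOKEN, TRUTHS_NAME

__all__ = ["load_dataset", "load_hidden_truths"]


def _load_image(path: str, target_size: int | None) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if target_size is not None and im.size != (target_size, target_size):
                im = im.resize((target_size, target_size), Image.BILINEAR)
            return np.asarray(im, dtype=np.float32) / 255.0
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot decode image file {path!r}") from exc


def load_dataset(manifest_path, image_root=None, target_size: int | None = None
                 ) -> tuple[LabeledSet, UnlabeledSet]:
    """Read a manifest into ``(labeled, unlabeled)`` float [0, 1] image sets.

    ``image_root`` defaults to the manifest's directory. Missing or
    undecodable files raise immediately, naming the file. An all-unlabeled
    manifest loads fine here (the trainer rejects it later).
    """
    manifest_path = os.fspath(manifest_path)
    root = image_root if image_root is not None else os.path.dirname(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("filename", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {manifest_path!r} missing column {col!r}")
    if df["filename"].duplicated().any():
        dup = df.loc[df["filename"].duplicated(), "filename"].iloc[0]
        raise ValueError(f"duplicate filename in manifest: {dup!r}")

    lab_imgs, lab_labels, unl_imgs = [], [], []
    for fname, label in zip(df["filename"], df["label"].astype(int)):
        path = os.path.join(root, fname)
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest references missing file {path!r}")
        img = _load_image(path, target_size)
        if label == UNLABELED_TOKEN:
            unl_imgs.append(img)
        elif label < 0:
            raise ValueError(f"invalid label {label} for {fname!r} "
                             f"(use {UNLABELED_TOKEN} for unlabeled)")
        else:
            lab_imgs.append(img)
            lab_labels.append(label)

    shape = (0, target_size or 0, target_size or 0, 3)
    labeled = LabeledSet(
        images=np.stack(lab_imgs) if lab_imgs else np.zeros(shape, np.float32),
        labels=np.asarray(lab_labels, dtype=np.intp))
    unlabeled = UnlabeledSet(
        images=np.stack(unl_imgs) if unl_imgs else np.zeros(shape, np.float32),
        true_labels=None)
    return labeled, unlabeled


def load_hidden_truths(dataset_dir) -> pd.DataFrame:
    """The evaluation-only side channel written next to a synthetic manifest."""
    path = os.path.join(os.fspath(dataset_dir), TRUTHS_NAME)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no hidden-truth file at {path!r}")
    return pd.read_csv(path)
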