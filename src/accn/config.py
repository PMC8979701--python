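"""YAML run configuration: schema-validated, unknown keys rejected.

A run config names the data (a manifest or a synthetic spec), the training
hyperparameters, the augmentation policy and the evaluation options. Every
CLI run writes its fully resolved config + seed + package version back into
the output directory for provenance, and that file re-parses to an equal
object (round-trip property).
"""

from __future__ import annotations

import os

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .augment import AugmentationPolicy, StrongPolicy, WeakPolicy
from .synthetic import SyntheticSpec
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WeakCfg(_Strict):
    crop_area: tuple[float, float] = (0.8, 1.0)
    flip_prob: float = Field(0.5, ge=0.0, le=1.0)


class StrongCfg(_Strict):
    n_ops: int = Field(2, ge=0)
    magnitude: float = Field(10.0, ge=0.0, le=30.0)
    fixed_sequence: tuple[str, ...] = ("cutout",)
    cutout_fraction: float = Field(0.25, gt=0.0, lt=1.0)


class AugmentationCfg(_Strict):
    weak: WeakCfg = WeakCfg()
    strong: StrongCfg = StrongCfg()
    K: int = Field(2, ge=1)

    def to_policy(self) -> AugmentationPolicy:
        return AugmentationPolicy(
            weak=WeakPolicy(crop_area=tuple(self.weak.crop_area),
                            flip_prob=self.weak.flip_prob),
            strong=StrongPolicy(n_ops=self.strong.n_ops,
                                magnitude=self.strong.magnitude,
                                fixed_sequence=tuple(self.strong.fixed_sequence),
                                cutout_fraction=self.strong.cutout_fraction),
            K=self.K)


class SyntheticCfg(_Strict):
    n_classes: int = 2
    n_labeled_per_class: int = 10
    n_unlabeled_per_class: int = 200
    image_size: int = 32
    separation: float = 4.0
    noise_sd: float = 0.1
    positive_fraction_unlabeled: float | None = None
    brightness_sd: float = 0.0
    contrast_jitter: float = 0.0
    seed: int = 0

    def to_spec(self) -> SyntheticSpec:
        return SyntheticSpec(**self.model_dump())


class DataCfg(_Strict):
    manifest: str | None = None       # path to CSV manifest
    image_root: str | None = None
    target_size: int | None = None
    synthetic: SyntheticCfg | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError("exactly one of data.manifest / data.synthetic required")
        return self


class TrainCfg(_Strict):
    epochs: int = Field(30, ge=1)
    batch_size: int = Field(8, ge=2)
    learning_rate: float = Field(1e-3, gt=0.0)
    optimizer: str = "adam"
    gammas: tuple[float, float, float] = (0.6, 0.3, 0.8)
    warmup_epochs: int = Field(1, ge=0)
    backbone: str = "tiny_cnn"
    widths: tuple[int, int, int] = (16, 32, 64)
    n_classes: int = Field(2, ge=2)
    l2_normalize_features: bool = False
    ac_norm: str = "l2sq"
    assign_from_memory: bool = True
    pseudolabel_refresh: str = "batch"
    epoch_refresh: bool = True
    disable_acl: bool = False
    disable_wcu: bool = False
    confidence_threshold: float = Field(0.95, gt=0.0, lt=1.0)
    steps_per_epoch: int | None = None
    restore_best: bool = False


class EvalCfg(_Strict):
    positive_class: int = 1


class RunConfig(_Strict):
    data: DataCfg
    train: TrainCfg = TrainCfg()
    augmentation: AugmentationCfg = AugmentationCfg()
    evaluation: EvalCfg = EvalCfg()
    seed: int = 0
    out_dir: str | None = None
    package_version: str | None = None  # filled in by the CLI on write

    def to_train_config(self) -> TrainConfig:
        return TrainConfig(policy=self.augmentation.to_policy(), seed=self.seed,
                           in_channels=3, **self.train.model_dump())


def load_config(path) -> RunConfig:
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path) -> None:
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
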