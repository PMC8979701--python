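"""Training loop: reproducibility, checkpoint resume, degenerate modes, errors."""

import numpy as np
import pandas as pd
import pytest

from accn.augment import AugmentationPolicy, StrongPolicy, WeakPolicy
from accn.synthetic import SyntheticSpec, generate_dataset
from accn.train import (
    ACCNModel,
    TrainConfig,
    TrainingDiverged,
    benchmark_protocol,
    run_ablation,
    ablation_table,
)

SMALL_WIDTHS = (4, 6, 8)


def tiny_data(seed=0, labeled=6, unlabeled=12, size=16):
    spec = SyntheticSpec(n_labeled_per_class=labeled // 2,
                         n_unlabeled_per_class=unlabeled // 2,
                         image_size=size, separation=6.0, seed=seed)
    return generate_dataset(spec)


def tiny_config(**overrides):
    defaults = dict(epochs=3, batch_size=4, widths=SMALL_WIDTHS,
                    warmup_epochs=1, seed=0)
    defaults.update(overrides)
    return TrainConfig(**defaults)


class TestReproducibility:
    def test_identical_history_under_same_seed(self):
        labeled, unlabeled = tiny_data()
        runs = []
        for _ in range(2):
            res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                            config=tiny_config()).fit()
            runs.append(res.history)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_different_seeds_differ(self):
        labeled, unlabeled = tiny_data()
        a = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                      config=tiny_config(seed=0)).fit()
        b = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                      config=tiny_config(seed=1)).fit()
        assert not np.allclose(a.history["total"], b.history["total"])


class TestCheckpointResume:
    def test_resume_retraces_uninterrupted_run(self, tmp_path):
        labeled, unlabeled = tiny_data(seed=3)
        full_cfg = tiny_config(epochs=4, seed=3)
        res_full = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                             config=full_cfg).fit()

        half_cfg = tiny_config(epochs=2, seed=3)
        res_half = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                             config=half_cfg).fit()
        ckpt = tmp_path / "ckpt.npz"
        res_half.save_checkpoint(ckpt)

        resumed = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                            config=full_cfg).fit(resume_from=ckpt)
        pd.testing.assert_frame_equal(
            resumed.history.reset_index(drop=True),
            res_full.history.reset_index(drop=True))
        for p_full, p_res in zip(res_full.network.params(), resumed.network.params()):
            np.testing.assert_array_equal(p_full.value, p_res.value)

    def test_checkpoint_keeps_centroid_memory(self, tmp_path):
        labeled, unlabeled = tiny_data(seed=5)
        res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                        config=tiny_config(seed=5)).fit()
        ckpt = tmp_path / "c.npz"
        res.save_checkpoint(ckpt)
        from accn.train import load_checkpoint_config
        cfg = load_checkpoint_config(ckpt)
        assert cfg.seed == 5 and cfg.widths == SMALL_WIDTHS


class TestDegenerateModes:
    def test_no_unlabeled_trains_supervised_only(self):
        labeled, _ = tiny_data()
        res = ACCNModel(labeled.images, labeled.labels, None,
                        config=tiny_config(gammas=(0, 0, 0))).fit()
        h = res.history
        assert (h["l_ac"] == 0).all() and (h["l_gc"] == 0).all() \
            and (h["l_pce"] == 0).all()
        np.testing.assert_allclose(h["total"], h["l_lce"], atol=1e-12)
        assert res.pseudo_labels_ is None

    def test_warmup_defers_clustering_losses(self):
        labeled, unlabeled = tiny_data()
        res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                        config=tiny_config(epochs=3, warmup_epochs=2)).fit()
        h = res.history
        assert (h.loc[h.epoch <= 2, "l_pce"] == 0).all()
        assert (h.loc[h.epoch == 3, "l_pce"] > 0).any()

    def test_disable_wcu_uses_confidence_path(self):
        labeled, unlabeled = tiny_data()
        res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                        config=tiny_config(disable_wcu=True)).fit()
        assert (res.history["l_gc"] == 0).all()
        assert res.pseudo_label_mask_ is not None

    def test_disable_acl_drops_consistency_loss(self):
        labeled, unlabeled = tiny_data()
        res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                        config=tiny_config(disable_acl=True)).fit()
        assert (res.history["l_ac"] == 0).all()


class TestErrors:
    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ACCNModel(np.zeros((0, 16, 16, 3), np.float32), np.zeros(0, int))

    def test_missing_class_rejected(self):
        labeled, _ = tiny_data()
        only_zero = labeled.labels == 0
        with pytest.raises(ValueError, match="class"):
            ACCNModel(labeled.images[only_zero], labeled.labels[only_zero],
                      config=tiny_config())

    def test_nan_input_aborts_with_diagnostics(self):
        labeled, _ = tiny_data()
        imgs = labeled.images.astype(np.float32) / 255.0
        imgs[0, 0, 0, 0] = np.nan
        with pytest.raises(TrainingDiverged) as err:
            ACCNModel(imgs, labeled.labels, None, config=tiny_config()).fit()
        assert "epoch" in err.value.diagnostics
        assert err.value.diagnostics["labeled_indices"]

    @pytest.mark.parametrize("kw, match", [
        (dict(batch_size=1), "batch_size"),
        (dict(learning_rate=0.0), "learning_rate"),
        (dict(optimizer="lbfgs"), "optimizer"),
        (dict(gammas=(-1, 0, 0)), "gammas"),
        (dict(confidence_threshold=1.0), "confidence_threshold"),
        (dict(pseudolabel_refresh="never"), "pseudolabel_refresh"),
    ])
    def test_config_validation(self, kw, match):
        with pytest.raises(ValueError, match=match):
            TrainConfig(**kw)


class TestBackboneSwap:
    @pytest.mark.parametrize("backbone", ["tiny_cnn", "resnet_small"])
    def test_training_loop_runs_unchanged(self, backbone):
        labeled, unlabeled = tiny_data()
        cfg = tiny_config(epochs=2, backbone=backbone)
        res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                        config=cfg).fit()
        assert len(res.history) == 2 * 3  # 2 epochs x ceil(12/4) steps
        assert res.network.config["backbone"] == backbone


class TestValidationTracking:
    def test_best_checkpoint_by_validation_accuracy(self):
        labeled, unlabeled = tiny_data(seed=7)
        val, _ = tiny_data(seed=8)
        cfg = tiny_config(epochs=3, restore_best=True, seed=7)
        res = ACCNModel(labeled.images, labeled.labels, unlabeled.images,
                        config=cfg, val_images=val.images,
                        val_labels=val.labels).fit()
        assert res.best_epoch is not None
        assert res.best_val_acc == res.epoch_history["val_acc"].max()

    def test_summary_mentions_backbone_and_losses(self):
        labeled, _ = tiny_data()
        res = ACCNModel(labeled.images, labeled.labels, None,
                        config=tiny_config()).fit()
        text = res.summary()
        assert "tiny_cnn" in text and "l_lce" in text


class TestAblationHarness:
    BENCH = dict(n_labeled_per_class=3, n_unlabeled_per_class=8,
                 n_test_per_class=10, image_size=16)

    def fast_cfg(self):
        return TrainConfig(epochs=2, batch_size=4, widths=SMALL_WIDTHS,
                           warmup_epochs=1, steps_per_epoch=3)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation variant"):
            run_ablation("dropout_only")

    def test_rows_have_metric_columns(self):
        row = run_ablation("no_wcu", seed=1, config=self.fast_cfg(),
                           benchmark_kwargs=self.BENCH)
        assert set(row) == {"variant", "seed", "ACC", "SEN", "SPE", "AUC"}
        assert 0.0 <= row["ACC"] <= 1.0

    def test_label_budget_sweep_writes_csv(self, tmp_path):
        out = tmp_path / "ablation.csv"
        table = ablation_table(["label_budget=4", "label_budget=8"], seeds=(0,),
                               config=self.fast_cfg(),
                               benchmark_kwargs=self.BENCH, out_csv=out)
        assert len(table) == 2
        assert out.exists()
        back = pd.read_csv(out)
        assert list(back["variant"]) == ["label_budget=4.0", "label_budget=8.0"]

    def test_positive_fraction_variant_runs(self):
        row = run_ablation("positive_fraction", seed=0, value=0.25,
                           config=self.fast_cfg(), benchmark_kwargs=self.BENCH)
        assert row["variant"] == "positive_fraction=0.25"

    def test_label_budget_requires_value(self):
        with pytest.raises(ValueError, match="label_budget"):
            run_ablation("label_budget", config=self.fast_cfg())


def test_benchmark_protocol_defaults():
    cfg = benchmark_protocol(seed=9)
    assert cfg.warmup_epochs == 10
    assert cfg.pseudolabel_refresh == "epoch"
    assert cfg.restore_best and cfg.seed == 9
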