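"""Split handling, epoch selection, training determinism and checkpoints."""

import numpy as np
import pandas as pd
import pytest

import condyseg as cs
from condyseg.classifier import ClassifierConfig
from condyseg.core import ValidationError, Volume
from condyseg.training import (
    SplitSpec,
    TrainConfig,
    draw_split,
    load_models,
    plan_cv_splits,
    save_models,
    scaled_train_config,
    select_best_epoch,
    train_models,
)
from condyseg.unet import UNetConfig


def tiny_cohort(seed=0, n_subjects=4):
    """Four small subjects (24 slices of 32x32) for fast training checks."""
    return cs.make_phantom_cohort(
        n_subjects,
        n_slices=24,
        in_plane=(32, 32),
        seed=seed,
        condyle_slice_fraction=0.5,
        thickness_range_mm=(0.9, 1.2),
        noise_sd=0.02,
        distractor_count=1,
    )


def tiny_configs():
    return (
        UNetConfig(depth=2, base_channels=4, input_shape=(32, 32)),
        ClassifierConfig(conv_channels=(4, 8, 8, 8), input_shape=(32, 32)),
    )


class TestSplits:
    def test_draw_split_ratio_and_disjointness(self):
        ids = [f"s{i}" for i in range(25)]
        split = draw_split(ids, (18, 5, 2), np.random.default_rng(0))
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (18, 5, 2)
        all_ids = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)
        assert len(all_ids) == 25

    def test_infeasible_ratio_errors(self):
        with pytest.raises(ValidationError, match="only 3"):
            draw_split(["a", "b", "c"], (18, 5, 2))

    def test_leakage_detected(self):
        split = SplitSpec(("a", "b"), ("b",), ("c",))
        with pytest.raises(ValidationError, match="leakage.*b"):
            split.validate()

    def test_plan_cv_splits_count_seeding_and_variety(self):
        ids = [f"s{i}" for i in range(25)]
        splits = plan_cv_splits(ids, (18, 5, 2), n_repeats=10, seed=7)
        again = plan_cv_splits(ids, (18, 5, 2), n_repeats=10, seed=7)
        assert len(splits) == 10
        assert [s.signature() for s in splits] == [s.signature() for s in again]
        assert len({s.signature() for s in splits}) > 1


class TestEpochSelection:
    def test_hand_examples(self):
        assert select_best_epoch([0.1, 0.5, 0.3]) == 2
        assert select_best_epoch([0.5, 0.5, 0.3]) == 1  # earliest tie wins
        assert select_best_epoch([0.9]) == 1

    def test_dataframe_input_and_column(self):
        h = pd.DataFrame({"val_iou_mean": [0.1, 0.2], "val_clf_accuracy": [0.9, 0.4]})
        assert select_best_epoch(h) == 2
        assert select_best_epoch(h, "val_clf_accuracy") == 1

    def test_matches_brute_force_on_random_histories(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(size=rng.integers(1, 15))
            best = 1 + max(range(len(v)), key=lambda i: (v[i], -i))
            assert select_best_epoch(v) == best

    def test_empty_history_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            select_best_epoch([])


class TestConfig:
    def test_defaults_are_full_scale_recipe(self):
        cfg = TrainConfig()
        assert cfg.optimizer == "adam"
        assert cfg.betas == (0.9, 0.999)
        assert cfg.learning_rate == 1e-4
        assert cfg.weight_decay == 1e-4
        assert cfg.batch_size == 1
        assert cfg.epochs == 30

    def test_scaled_recipe_overrides(self):
        cfg = scaled_train_config(seed=5)
        assert cfg.epochs == 10 and cfg.learning_rate == 1e-3 and cfg.seed == 5

    def test_validation(self):
        with pytest.raises(ValidationError, match="optimizer"):
            TrainConfig(optimizer="sgd").validate()
        with pytest.raises(ValidationError, match="positive"):
            TrainConfig(epochs=0).validate()


@pytest.fixture(scope="module")
def run():
    cohort = tiny_cohort()
    split = draw_split([s.subject_id for s in cohort], (2, 1, 1),
                       np.random.default_rng(1))
    cfg = scaled_train_config(seed=0, epochs=2)
    ucfg, ccfg = tiny_configs()
    models = train_models(cohort, split, cfg, ucfg, ccfg)
    return cohort, split, cfg, models


class TestTrainModels:

    def test_history_schema_and_length(self, run):
        _, _, cfg, models = run
        h = models.history
        assert list(h["epoch"]) == list(range(1, cfg.epochs + 1))
        for col in ("unet_train_loss", "clf_train_loss", "val_iou_marrow",
                    "val_iou_cortical", "val_iou_mean", "val_clf_accuracy"):
            assert col in h.columns and np.isfinite(h[col]).all()
        assert 1 <= models.best_unet_epoch <= cfg.epochs
        assert 1 <= models.best_classifier_epoch <= cfg.epochs

    def test_unet_pool_restricted_to_condyle_slices(self, run):
        cohort, split, _, models = run
        subjects = {s.subject_id: s for s in cohort}
        n_condyle = sum(int(subjects[i].presence.values.sum()) for i in split.train_ids)
        n_all = sum(subjects[i].volume.n_slices for i in split.train_ids)
        assert models.n_unet_train_slices == n_condyle
        assert models.n_classifier_train_slices == n_all
        assert n_condyle < n_all

    def test_same_seed_reproduces_weights(self, run):
        cohort, split, cfg, models = run
        again = train_models(cohort, split, cfg, *tiny_configs())
        for k, v in models.unet.state_arrays().items():
            assert np.array_equal(v, again.unet.state_arrays()[k]), k
        for k, v in models.classifier.state_arrays().items():
            assert np.array_equal(v, again.classifier.state_arrays()[k]), k
        pd.testing.assert_frame_equal(models.history, again.history)

    def test_checkpoint_round_trip(self, run, tmp_path):
        cohort, _, _, models = run
        path = tmp_path / "ckpt.npz"
        save_models(models, path)
        loaded = load_models(path)
        assert loaded.best_unet_epoch == models.best_unet_epoch
        # identical predictions on a held-out subject
        s = cohort[0]
        from condyseg.classifier import predict_presence
        from condyseg.unet import segment_slices

        p1 = predict_presence(models.classifier, s.volume)
        p2 = predict_presence(loaded.classifier, s.volume)
        assert np.allclose(p1.scores, p2.scores)
        r1 = segment_slices(models.unet, s.volume, s.presence)
        r2 = segment_slices(loaded.unet, s.volume, s.presence)
        assert np.allclose(r1.prob_maps, r2.prob_maps)


def test_monte_carlo_cv_bookkeeping():
    """Two tiny repeats: per-repeat seeds, report tagging, frame schema."""
    cohort = tiny_cohort(seed=3)
    ucfg, ccfg = tiny_configs()
    cfg = scaled_train_config(seed=10, epochs=1)
    result = cs.monte_carlo_cv(cohort, ratio=(2, 1, 1), n_repeats=2, cfg=cfg,
                               unet_config=ucfg, clf_config=ccfg)
    assert result.seeds == [10, 11]
    assert len(result.splits) == 2
    assert len(result.reports) == 2  # one test subject per repeat
    assert {r.experiment for r in result.reports} == {"repeat000", "repeat001"}
    f = result.frame()
    assert set(f.columns) == {"repeat", "subject", "class", "iou", "hausdorff_mm"}
    assert len(f) == 4  # 2 repeats x 1 subject x 2 classes
    assert ((0 <= f["iou"]) & (f["iou"] <= 1)).all()
    summary = result.summary()
    for cls in ("marrow", "cortical"):
        expect = f[f["class"] == cls]["iou"].mean()
        assert summary.loc[cls, ("iou", "mean")] == pytest.approx(expect)
    assert result.last_models is not None
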