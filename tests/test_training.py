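"""Loss, class weighting, split protocol, early stopping and determinism."""

import numpy as np
import pytest

from holoclass import (
    AmplitudePhasePair,
    ClassWeights,
    HologramSample,
    ModelConfig,
    OpticalParams,
    TrainConfig,
    compute_class_weights,
    inflate_to_3d,
    make_splits,
    run_cv,
    train_model,
    weighted_nll_loss,
)
from holoclass.models import HologramClassifier
from holoclass.synthetic import DatasetManifest
import pandas as pd


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        w = compute_class_weights([0, 0, 1, 1, 2, 2], 3)
        assert np.allclose(w.weights, 1.0)

    def test_two_class_example(self):
        labels = [0] * 10 + [1] * 30
        w = compute_class_weights(labels, 2)
        assert np.allclose(w.weights, [1.5, 0.5])

    def test_three_class_example(self):
        labels = [0, 1, 2, 2]
        w = compute_class_weights(labels, 3)
        assert np.allclose(w.weights, [1.2, 1.2, 0.6])

    def test_mean_normalisation_invariant(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, 200)
        w = compute_class_weights(labels, 5)
        assert w.weights.mean() == pytest.approx(1.0)

    def test_absent_class_error_names_it(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            compute_class_weights([0, 1, 0, 1], 3)

    def test_non_positive_weights_rejected(self):
        with pytest.raises(ValueError):
            ClassWeights(weights=np.array([1.0, 0.0]))


def _log_probs(rows):
    return np.log(np.asarray(rows, dtype=np.float64))


class TestWeightedNLL:
    def test_perfect_prediction_has_zero_loss(self):
        lp = np.full((3, 4), -50.0)
        lp[np.arange(3), [0, 1, 2]] = 0.0
        w = ClassWeights(np.ones(4))
        assert weighted_nll_loss(lp, [0, 1, 2], w) == pytest.approx(0.0)

    def test_uniform_prediction_over_seven_classes(self):
        lp = np.full((5, 7), np.log(1 / 7))
        w = ClassWeights(np.ones(7))
        assert weighted_nll_loss(lp, [0, 3, 6, 2, 5], w) == pytest.approx(np.log(7))

    def test_weighted_hand_example(self):
        lp = _log_probs([[0.8, 0.2], [0.4, 0.6]])
        w = ClassWeights(np.array([1.5, 0.5]))
        expected = (1.5 * -np.log(0.8) + 0.5 * -np.log(0.6)) / 2.0
        assert weighted_nll_loss(lp, [0, 1], w) == pytest.approx(expected, abs=1e-10)

    def test_plain_mean_reduction(self):
        lp = _log_probs([[0.8, 0.2], [0.4, 0.6]])
        w = ClassWeights(np.array([1.5, 0.5]))
        expected = (1.5 * -np.log(0.8) + 0.5 * -np.log(0.6)) / 2.0
        assert weighted_nll_loss(lp, [0, 1], w, reduction="mean") == pytest.approx(expected)

    def test_equals_weighted_cross_entropy_on_raw_scores(self):
        """log-softmax + NLL == cross-entropy on pre-normalisation scores."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=(16, 5)) * 3
        labels = rng.integers(0, 5, 16)
        w = ClassWeights(rng.uniform(0.5, 2.0, 5) / rng.uniform(0.5, 2.0, 5).mean())
        lp = z - np.log(np.exp(z - z.max(1, keepdims=True)).sum(1, keepdims=True)) - z.max(1, keepdims=True)
        wi = w.weights[labels]
        ce = np.sum(wi * (np.log(np.exp(z).sum(axis=1)) - z[np.arange(16), labels])) / wi.sum()
        assert weighted_nll_loss(lp, labels, w) == pytest.approx(ce, abs=1e-6)

    def test_unit_weights_match_unweighted_mean(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(8, 3))
        lp = z - np.log(np.exp(z).sum(1, keepdims=True))
        labels = rng.integers(0, 3, 8)
        w = ClassWeights(np.ones(3))
        plain = -np.mean(lp[np.arange(8), labels])
        assert weighted_nll_loss(lp, labels, w) == pytest.approx(plain)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            weighted_nll_loss(np.zeros((2, 3)), [0, 3], ClassWeights(np.ones(3)))


class TestMakeSplits:
    def test_85_15_split_and_five_equal_folds(self, balanced_100_manifest):
        manifest, _ = balanced_100_manifest
        cfg = TrainConfig(seed=0, n_folds=5)
        test_idx, pairs = make_splits(manifest, cfg)
        assert len(test_idx) == 15
        assert len(pairs) == 5
        for p in pairs:
            assert len(p.val_idx) == 17
            assert len(p.train_idx) == 68

    def test_folds_partition_training_set(self, balanced_100_manifest):
        manifest, _ = balanced_100_manifest
        cfg = TrainConfig(seed=0, n_folds=5)
        test_idx, pairs = make_splits(manifest, cfg)
        train_all = set(range(100)) - set(test_idx.tolist())
        val_union = set()
        for p in pairs:
            fold_val = set(p.val_idx.tolist())
            assert fold_val.isdisjoint(val_union)
            val_union |= fold_val
            assert set(p.train_idx.tolist()) == train_all - fold_val
        assert val_union == train_all

    def test_stratification_preserves_class_balance(self, balanced_100_manifest):
        manifest, _ = balanced_100_manifest
        cfg = TrainConfig(seed=0, n_folds=5)
        test_idx, _ = make_splits(manifest, cfg)
        labels = manifest.records["label"].to_numpy()[test_idx]
        counts = pd.Series(labels).value_counts()
        assert set(counts) == {3, 4}  # 15 test samples over 4 balanced classes

    def test_deterministic_given_seed(self, balanced_100_manifest):
        manifest, _ = balanced_100_manifest
        cfg = TrainConfig(seed=5, n_folds=5)
        t1, p1 = make_splits(manifest, cfg)
        t2, p2 = make_splits(manifest, cfg)
        assert np.array_equal(t1, t2)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.train_idx, b.train_idx)
            assert np.array_equal(a.val_idx, b.val_idx)

    def test_too_small_class_rejected(self):
        records = pd.DataFrame(
            {"id": [f"s{i}" for i in range(12)],
             "label": ["TRC1"] * 10 + ["SP"] * 2,
             "true_focus_um": 0.0, "split": "", "seed": 0}
        )
        manifest = DatasetManifest(records=records, class_counts={"TRC1": 10, "SP": 2})
        with pytest.raises(ValueError, match="fewer members"):
            make_splits(manifest, TrainConfig(n_folds=5))


def _separable_samples(n_per_class=16, size=32, seed=0):
    """Two trivially separable classes: dim vs bright uniform amplitude."""
    rng = np.random.default_rng(seed)
    optics = OpticalParams()
    samples = []
    for label, level in (("TRC1", 0.8), ("SP", 1.2)):
        for _ in range(n_per_class):
            amp = np.full((size, size), level) + rng.normal(0, 0.02, (size, size))
            pair = AmplitudePhasePair(amplitude=np.abs(amp), phase=np.zeros((size, size)))
            samples.append(HologramSample(pair=pair, label=label,
                                          focus_offset_um=0.0, params=optics))
    records = pd.DataFrame(
        {"id": [f"s{i:03d}" for i in range(len(samples))],
         "label": [s.label for s in samples],
         "true_focus_um": 0.0, "split": "", "seed": 0}
    )
    manifest = DatasetManifest(records=records,
                               class_counts={"TRC1": n_per_class, "SP": n_per_class})
    return manifest, samples


TINY_MODEL = ModelConfig(in_channels=2, n_classes=2, block_channels=(2, 2, 3, 3),
                         dense_hidden=8, dropout_p=0.0)


class TestTrainModel:
    def test_separable_task_reaches_high_accuracy(self):
        manifest, samples = _separable_samples()
        cfg = TrainConfig(model_dims=2, n_folds=2, batch_size=4, lr=3e-3,
                          weight_decay=0.0, max_epochs=30, patience_epochs=30,
                          seed=0, use_geometric_augment=False)
        _, pairs = make_splits(manifest, cfg)
        model, history = train_model(samples, pairs[0], TINY_MODEL, cfg, ("TRC1", "SP"))
        assert max(history.train_acc) >= 0.95
        assert history.best_epoch <= history.stopped_epoch

    def test_early_stopping_restores_best_epoch_weights(self):
        manifest, samples = _separable_samples()
        cfg = TrainConfig(model_dims=2, n_folds=2, batch_size=4, lr=3e-3,
                          weight_decay=0.0, max_epochs=12, patience_epochs=3,
                          seed=0, use_geometric_augment=False)
        _, pairs = make_splits(manifest, cfg)
        model, history = train_model(samples, pairs[0], TINY_MODEL, cfg, ("TRC1", "SP"))
        # recompute the validation loss of the returned weights: must equal the
        # recorded minimum (the restored state includes batch-norm statistics)
        from holoclass.training import _BatchBuilder, _predict, _labels_to_ids

        builder = _BatchBuilder(samples, cfg)
        ids = _labels_to_ids([s.label for s in samples], ("TRC1", "SP"))
        lp = _predict(model, builder, pairs[0].val_idx, cfg.batch_size)
        w = compute_class_weights(ids[pairs[0].train_idx], 2)
        val_loss = weighted_nll_loss(lp, ids[pairs[0].val_idx], w)
        assert val_loss == pytest.approx(min(history.val_loss), abs=1e-6)
        assert history.val_loss[history.best_epoch] == pytest.approx(min(history.val_loss))
        # stopping rule: no more than patience epochs beyond the best one
        assert history.stopped_epoch - history.best_epoch <= cfg.patience_epochs

    def test_training_is_deterministic_given_seed(self):
        manifest, samples = _separable_samples()
        cfg = TrainConfig(model_dims=2, n_folds=2, batch_size=4, lr=3e-3,
                          max_epochs=3, patience_epochs=3, seed=7)
        _, pairs = make_splits(manifest, cfg)
        _, h1 = train_model(samples, pairs[0], TINY_MODEL, cfg, ("TRC1", "SP"))
        _, h2 = train_model(samples, pairs[0], TINY_MODEL, cfg, ("TRC1", "SP"))
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss


class TestRunCV:
    def test_returns_one_model_per_fold_with_distinct_val_folds(self):
        manifest, samples = _separable_samples()
        cfg = TrainConfig(model_dims=2, n_folds=3, batch_size=4, lr=3e-3,
                          max_epochs=2, patience_epochs=2, seed=0)
        test_idx, models, histories = run_cv(samples, manifest, TINY_MODEL, cfg,
                                             ("TRC1", "SP"))
        assert len(models) == 3 and len(histories) == 3
        _, pairs = make_splits(manifest, cfg)
        vals = [tuple(p.val_idx.tolist()) for p in pairs]
        assert len(set(vals)) == 3

    def test_warm_start_from_planar_model(self):
        manifest, samples = _separable_samples()
        cfg2 = TrainConfig(model_dims=2, n_folds=2, batch_size=4, lr=3e-3,
                           max_epochs=2, patience_epochs=2, seed=0)
        _, pairs = make_splits(manifest, cfg2)
        m2, _ = train_model(samples, pairs[0], TINY_MODEL, cfg2, ("TRC1", "SP"))
        cfg3 = TrainConfig(model_dims=3, n_folds=2, batch_size=4, lr=1e-3,
                           max_epochs=1, patience_epochs=1, seed=0, n_steps=1)
        m3, h3 = train_model(samples, pairs[0], TINY_MODEL, cfg3, ("TRC1", "SP"),
                             init_model=m2)
        assert m3.dims == 3
        assert len(h3.train_loss) == 1


class TestInflation:
    def test_inflated_model_reproduces_planar_output_per_slice(self):
        """With the head's depth pooling removed from the comparison, the
        inflated network's per-slice features equal the planar network's."""
        rng = np.random.default_rng(0)
        cfg = ModelConfig(in_channels=2, n_classes=3, block_channels=(2, 3, 3, 4),
                          dense_hidden=6, dropout_p=0.0)
        m2 = HologramClassifier(cfg, dims=2, seed=1)
        m3 = inflate_to_3d(m2)
        x2 = rng.normal(size=(1, 2, 32, 32)).astype(np.float32)
        vol = np.repeat(x2[:, :, None], 5, axis=2)  # 5 identical slices
        feats2 = np.moveaxis(x2, 1, -1)
        for b in m2.blocks:
            feats2 = b.forward(feats2, train=False)
        feats3 = np.moveaxis(vol, 1, -1)
        for b in m3.blocks:
            feats3 = b.forward(feats3, train=False)
        # interior slices see a full depth neighbourhood of identical planes
        assert np.allclose(feats3[:, 2], feats2, atol=1e-5)
        # identical slices make depth pooling transparent: full outputs agree
        assert np.allclose(m3.forward(vol), m2.forward(x2), atol=1e-4)

    def test_inflate_rejects_volumetric_input_model(self):
        cfg = ModelConfig(in_channels=2, n_classes=3, block_channels=(2, 2, 2, 2),
                          dense_hidden=4)
        m3 = HologramClassifier(cfg, dims=3, seed=0)
        with pytest.raises(ValueError):
            inflate_to_3d(m3)
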