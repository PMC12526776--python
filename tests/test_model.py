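"""Classifier architectures, training loop, tuner, and the numerics
behind them (including a finite-difference check of backpropagation)."""

import dataclasses

import numpy as np
import pytest

from runsurf import nn
from runsurf.model import (
    ConfigError,
    ModelConfig,
    SearchSpace,
    build_baseline,
    build_final,
    predict,
    train,
    tune,
    FILTER_GRID,
)
from runsurf.preprocessing import SegmentTensor
from runsurf.splitting import split_subject_dependent

TINY = ModelConfig(
    n_conv_layers=1,
    filters=(32,),
    kernel_size=3,
    dropout=0.0,
    dense_units=8,
    batch_size=50,
    max_epochs=3,
    patience=2,
)


def _toy_tensor(n=120, frames=30, channels=4, seed=0):
    """Linearly separable two-class data: class shifts channel means."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    values = rng.normal(0, 1, size=(n, frames, channels)).astype(np.float32)
    values += labels[:, None, None] * 1.5
    subjects = np.array([f"S{i % 6}" for i in range(n)])
    return SegmentTensor(
        values=values,
        labels=labels,
        subjects=subjects,
        channel_names=[f"c{j}" for j in range(channels)],
    )


class TestConfigValidation:
    def test_conv_layer_range(self):
        for n in (1, 2, 3, 4):
            ModelConfig(n_conv_layers=n, filters=(32,) * n)
        with pytest.raises(ConfigError, match="n_conv_layers"):
            ModelConfig(n_conv_layers=5, filters=(32,) * 5)

    def test_filters_on_grid(self):
        with pytest.raises(ConfigError, match="filters"):
            ModelConfig(filters=(300, 64))
        with pytest.raises(ConfigError, match="filters"):
            ModelConfig(filters=(48, 64))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("kernel_size", 7),
            ("dropout", 0.35),
            ("learning_rate", 0.5),
            ("optimizer", "adagrad"),
            ("batch_size", 128),
            ("regularization", "l3"),
        ],
    )
    def test_out_of_grid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            ModelConfig(**{field: value})


class TestArchitectures:
    def test_softmax_head_outputs_probabilities(self):
        net = build_baseline(100, 6, TINY)
        x = np.random.default_rng(0).normal(size=(5, 100, 6))
        probs = net.predict_proba(x)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_fixed_seed_identical_initialization(self):
        a = build_final(60, 4, TINY)
        b = build_final(60, 4, TINY)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_batch_norm_flag_toggles_stage(self):
        with_bn = build_final(60, 4, TINY)
        without = build_final(
            60, 4, dataclasses.replace(TINY, batch_norm_flag=False)
        )
        assert any(d == "BatchNorm" for d in with_bn.describe())
        assert not any(d == "BatchNorm" for d in without.describe())

    def test_baseline_has_pooling_final_does_not(self):
        base = build_baseline(60, 4, TINY)
        final = build_final(60, 4, TINY)
        assert any(d.startswith("MaxPool") for d in base.describe())
        assert not any(d.startswith("MaxPool") for d in final.describe())

    def test_l2_changes_training_loss_on_fixed_batch(self):
        x = np.random.default_rng(1).normal(size=(20, 30, 4)).astype(np.float32)
        y = np.random.default_rng(2).integers(0, 2, size=20)
        plain = build_baseline(30, 4, TINY)
        loss0, _ = plain.loss_and_grads(x, y, np.random.default_rng(0))
        reg = build_baseline(30, 4, TINY)
        loss1, _ = reg.loss_and_grads(
            x, y, np.random.default_rng(0), l2=1e-2
        )
        assert loss1 > loss0


def test_backprop_matches_finite_differences():
    """Central-difference gradient check on a small conv/BN/dense net."""
    cfg = dataclasses.replace(TINY, dropout=0.0)
    net = build_final(12, 2, cfg)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(8, 12, 2)).astype(np.float32)
    y = rng.integers(0, 2, size=8)

    def loss_at():
        logits = net.forward(x, training=True)
        probs = nn.softmax(logits)
        return float(-np.mean(np.log(probs[np.arange(8), y] + 1e-12)))

    net.loss_and_grads(x, y, rng)
    checked = 0
    for layer in net.layers:
        for name, w in layer.params.items():
            g = layer.grads[name]
            flat = w.reshape(-1)
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                eps = 1e-2
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                down = loss_at()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = g.reshape(-1)[idx]
                assert abs(numeric - analytic) <= 2e-2 + 0.05 * abs(numeric), (
                    layer.describe(), name, idx, numeric, analytic,
                )
                checked += 1
    assert checked >= 12


class TestTraining:
    def test_early_stopping_respects_patience(self):
        tensor = _toy_tensor()
        split = split_subject_dependent(tensor.n_segments, seed=0)
        cfg = dataclasses.replace(TINY, max_epochs=40, patience=5)
        fitted = train(build_baseline(30, 4, cfg), tensor, split, cfg)
        assert fitted.stopped_epoch <= fitted.best_epoch + cfg.patience
        assert fitted.stopped_epoch <= cfg.max_epochs
        lengths = {len(v) for v in fitted.history.values()}
        assert lengths == {fitted.stopped_epoch}

    def test_seeded_runs_reproduce_history(self):
        tensor = _toy_tensor()
        split = split_subject_dependent(tensor.n_segments, seed=0)
        runs = [
            train(build_baseline(30, 4, TINY), tensor, split, TINY)
            for _ in range(2)
        ]
        assert runs[0].stopped_epoch == runs[1].stopped_epoch
        for key in runs[0].history:
            np.testing.assert_allclose(
                runs[0].history[key], runs[1].history[key]
            )

    def test_separable_data_is_learned(self):
        tensor = _toy_tensor()
        split = split_subject_dependent(tensor.n_segments, seed=0)
        cfg = dataclasses.replace(TINY, max_epochs=25, patience=10)
        fitted = train(build_baseline(30, 4, cfg), tensor, split, cfg)
        test = tensor.subset(split.test)
        probs, labels = predict(fitted, test)
        assert np.mean(labels == test.labels) >= 0.9
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_train_accuracy_close_to_validation(self):
        tensor = _toy_tensor()
        split = split_subject_dependent(tensor.n_segments, seed=0)
        cfg = dataclasses.replace(TINY, max_epochs=25, patience=10)
        fitted = train(build_baseline(30, 4, cfg), tensor, split, cfg)
        _, labels = predict(fitted, tensor.subset(split.train))
        train_acc = np.mean(labels == tensor.labels[split.train])
        best = int(np.argmin(fitted.history["val_loss"]))
        assert train_acc >= fitted.history["val_accuracy"][best] - 0.05

    def test_prediction_is_stateless_under_permutation(self):
        tensor = _toy_tensor(n=40)
        split = split_subject_dependent(tensor.n_segments, seed=0)
        fitted = train(build_baseline(30, 4, TINY), tensor, split, TINY)
        probs, _ = predict(fitted, tensor)
        perm = np.random.default_rng(1).permutation(tensor.n_segments)
        probs_perm, _ = predict(fitted, tensor.subset(perm))
        np.testing.assert_allclose(probs[perm], probs_perm, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        tensor = _toy_tensor(n=40)
        split = split_subject_dependent(tensor.n_segments, seed=0)
        fitted = train(build_baseline(30, 4, TINY), tensor, split, TINY)
        with pytest.raises(ValueError, match="shape"):
            predict(fitted, np.zeros((3, 31, 4), dtype=np.float32))


class TestTune:
    def test_budget_one_returns_sampled_config(self):
        tensor = _toy_tensor(n=60)
        split = split_subject_dependent(tensor.n_segments, seed=0)
        space = SearchSpace(
            n_conv_layers=(1,), filters=(32,), batch_size=(50,)
        )
        best, log = tune(space, tensor, split, budget=1, seed=0, base_config=TINY)
        assert len(log) == 1
        assert best == log[0].config

    def test_samples_stay_on_grid(self):
        space = SearchSpace()
        base = ModelConfig()
        rng = np.random.default_rng(0)
        for _ in range(40):
            cfg = space.sample(rng, base)
            assert all(f in FILTER_GRID for f in cfg.filters)
            assert cfg.kernel_size in (3, 4, 5)
            assert 1e-4 <= cfg.learning_rate <= 1e-2
            assert cfg.batch_size in (50, 100, 200, 300)

    def test_best_score_non_decreasing_in_budget(self):
        tensor = _toy_tensor(n=60)
        split = split_subject_dependent(tensor.n_segments, seed=0)
        space = SearchSpace(
            n_conv_layers=(1,), filters=(32, 64), batch_size=(50,),
            kernel_size=(3,),
        )
        base = dataclasses.replace(TINY, max_epochs=2, patience=2)
        scores = []
        for budget in (1, 2, 3):
            _, log = tune(space, tensor, split, budget, seed=0, base_config=base)
            scores.append(max(t.val_accuracy for t in log))
        assert scores == sorted(scores)

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            SearchSpace(filters=())
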