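import dataclasses

import numpy as np
import pytest

from maxminus_dropout.autodiff import zero_grads
from maxminus_dropout.backbone import BackboneConfig, build_backbone
from maxminus_dropout.data_model import ClinicalTable
from maxminus_dropout.imputation import ImputationPolicy
from maxminus_dropout.losses import bidirectional_kl, dual_cross_entropy
from maxminus_dropout.optim import build_optimizer
from maxminus_dropout.sampling import MiniBatch
from maxminus_dropout.synthetic_data import custom_spec, generate_clinical_dataset
from maxminus_dropout.training import (TrainConfig, derive_rng, prepare_tables,
                                       run_ablation, run_trials, train, train_step)


def toy_tables(seed=0, n=80, n_classes=2, separation=2.0):
    spec = custom_spec(n_rows=n, n_boolean=5, n_continuous=2,
                       n_classes=n_classes, separation=separation, seed=seed)
    dataset = generate_clinical_dataset(spec)
    return prepare_tables(dataset, ImputationPolicy(), 0.7, seed=seed)


SMALL_BACKBONE = BackboneConfig(n_features=7, n_classes=2, hidden_size=8,
                                depth=2, dropout_rate=0.3)


def snapshot(model):
    return [p.data.copy() for p in model.params]


def reference_loop(train_table, config, backbone_config, loss_kind):
    """Independent training loop computing only the named objective.

    loss_kind: 'dual_ce' (two dropout passes, CE only), 'rdrop'
    (dual CE + alpha * bidirectional KL), or 'plain_ce' (a single
    deterministic pass, CE counted once per pass of the dual scheme).
    Shares the package's seed-derivation scheme so trajectories are
    comparable step for step.
    """
    model = build_backbone(backbone_config, seed=config.base_seed)
    opt = build_optimizer(config.optimizer_name, model.params, config.learning_rate)
    x, y = train_table.values, train_table.label_indices()
    n = x.shape[0]
    for epoch in range(config.epochs):
        perm = derive_rng(config.base_seed, 1, epoch).permutation(n)
        for step, start in enumerate(range(0, n, config.batch_size)):
            idx = perm[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            key = (config.base_seed, 2, epoch, step)
            if loss_kind == "plain_ce":
                p = model.forward(xb, train=False)
                rows = np.arange(len(idx))
                loss = (-(p.clip_min(1e-12)[rows, yb].log())).mean() * 2.0
            else:
                p1 = model.forward(xb, derive_rng(*key, 0), train=True)
                p2 = model.forward(xb, derive_rng(*key, 1), train=True)
                loss = dual_cross_entropy(p1, p2, yb)
                if loss_kind == "rdrop":
                    loss = loss + config.alpha * bidirectional_kl(p1, p2)
            zero_grads(model.params)
            loss.backward()
            opt.step()
    return model


class TestReductions:
    """With pieces of the objective switched off, the full training step
    must collapse exactly onto the simpler schemes."""

    def test_alpha_zero_reproduces_dual_pass_ce(self):
        train_t, test_t = toy_tables()
        config = TrainConfig(alpha=0.0, batch_size=16, epochs=3, base_seed=3)
        model = build_backbone(SMALL_BACKBONE, seed=3)
        train(model, train_t, test_t, config)
        reference = reference_loop(train_t, config, SMALL_BACKBONE, "dual_ce")
        for p, q in zip(model.params, reference.params):
            assert np.array_equal(p.data, q.data)

    def test_dropping_negative_term_reproduces_rdrop(self):
        train_t, test_t = toy_tables()
        config = TrainConfig(alpha=1.0, include_negative=False, batch_size=16,
                             epochs=3, base_seed=4)
        model = build_backbone(SMALL_BACKBONE, seed=4)
        train(model, train_t, test_t, config)
        reference = reference_loop(train_t, config, SMALL_BACKBONE, "rdrop")
        for p, q in zip(model.params, reference.params):
            assert np.array_equal(p.data, q.data)

    def test_zero_dropout_and_alpha_reproduce_plain_ce(self):
        train_t, test_t = toy_tables()
        backbone = dataclasses.replace(SMALL_BACKBONE, dropout_rate=0.0)
        config = TrainConfig(alpha=0.0, batch_size=16, epochs=3, base_seed=5)
        model = build_backbone(backbone, seed=5)
        train(model, train_t, test_t, config)
        reference = reference_loop(train_t, config, backbone, "plain_ce")
        for p, q in zip(model.params, reference.params):
            assert np.allclose(p.data, q.data, rtol=0, atol=0)


class TestTrainStep:
    def test_returns_consistent_breakdown(self):
        train_t, _ = toy_tables()
        model = build_backbone(SMALL_BACKBONE, seed=0)
        opt = build_optimizer("adam", model.params, 1e-3)
        batch = MiniBatch(train_t.values[:16], train_t.label_indices()[:16])
        config = TrainConfig(alpha=1.5, batch_size=16, epochs=1)
        bd = train_step(model, batch, config, opt, (0, 2, 0, 0))
        assert bd.l_ce >= 0 and bd.l_kl >= 0 and 0 <= bd.l_ng <= 1
        assert bd.total == pytest.approx(bd.l_ce + 1.5 * (bd.l_kl - bd.l_ng))

    def test_losses_finite_on_random_batches(self):
        rng = np.random.default_rng(0)
        model = build_backbone(SMALL_BACKBONE, seed=0)
        opt = build_optimizer("adam", model.params, 1e-4)
        config = TrainConfig(alpha=4.0, batch_size=8, epochs=1)
        for step in range(100):
            x = rng.random((8, 7))
            y = rng.integers(0, 2, size=8)
            bd = train_step(model, MiniBatch(x, y), config, opt, (1, 2, 0, step))
            assert np.isfinite(bd.total)


class TestTrainLoop:
    def test_zero_epochs_leaves_model_unchanged(self):
        train_t, test_t = toy_tables()
        model = build_backbone(SMALL_BACKBONE, seed=0)
        before = snapshot(model)
        history = train(model, train_t, test_t,
                        TrainConfig(epochs=0, batch_size=16))
        assert history.steps == [] and history.epoch_accuracy == []
        for p, b in zip(model.params, before):
            assert np.array_equal(p.data, b)

    def test_history_reproducible_with_fixed_seed(self):
        train_t, test_t = toy_tables()
        config = TrainConfig(batch_size=16, epochs=2, base_seed=11)
        h1 = train(build_backbone(SMALL_BACKBONE, seed=11), train_t, test_t, config)
        h2 = train(build_backbone(SMALL_BACKBONE, seed=11), train_t, test_t, config)
        assert h1.epoch_accuracy == h2.epoch_accuracy
        assert [s.total for s in h1.steps] == [s.total for s in h2.steps]

    def test_mean_epoch_loss_decreases_on_separable_blobs(self):
        train_t, test_t = toy_tables(seed=1, n=200, separation=3.0)
        config = TrainConfig(alpha=1.0, batch_size=32, epochs=20, base_seed=1,
                             learning_rate=1e-2)
        model = build_backbone(SMALL_BACKBONE, seed=1)
        history = train(model, train_t, test_t, config)
        losses = history.epoch_mean_total
        # monotone trend: every epoch improves on the running best so far
        running_best = losses[0]
        improvements = 0
        for value in losses[1:]:
            if value < running_best:
                improvements += 1
                running_best = value
        assert improvements >= 15
        assert losses[-1] < losses[0]

    def test_incomplete_table_rejected(self, small_table):
        model = build_backbone(BackboneConfig(n_features=4, n_classes=2), seed=0)
        with pytest.raises(ValueError, match="impute"):
            train(model, small_table, small_table, TrainConfig(epochs=1))


class TestRunTrials:
    def test_single_trial_has_zero_std(self):
        train_t, test_t = toy_tables()
        config = TrainConfig(batch_size=16, epochs=2, n_trials=1, base_seed=0)
        summary = run_trials(config, SMALL_BACKBONE, lambda seed: (train_t, test_t))
        assert summary.accuracy_std == 0.0
        assert summary.accuracy_mean == summary.accuracies[0]

    def test_mean_of_identical_trials_is_single_value(self):
        train_t, test_t = toy_tables()
        config = TrainConfig(batch_size=16, epochs=1, n_trials=3, base_seed=0)
        # force identical trials by ignoring the seed in both data and training
        summaries = run_trials(config, SMALL_BACKBONE, lambda seed: (train_t, test_t))
        assert len(summaries.accuracies) == 3


@pytest.fixture(scope="module")
def tiny_setup():
    spec = custom_spec(n_rows=60, n_boolean=5, n_continuous=2, n_classes=2,
                       separation=2.0, seed=0, missing_count=10)
    dataset = generate_clinical_dataset(spec)
    config = TrainConfig(batch_size=16, epochs=1, n_trials=1, base_seed=0)
    return dataset, config


class TestAblation:
    @pytest.mark.parametrize("axis,n_rows", [
        ("dropout_rate", 5), ("alpha", 6), ("negative_strategy", 3),
        ("negative_loss", 2), ("imputation", 4),
    ])
    def test_grid_sizes_match_protocol(self, tiny_setup, axis, n_rows):
        dataset, config = tiny_setup
        table = run_ablation(axis, config, SMALL_BACKBONE, dataset,
                             ImputationPolicy())
        assert len(table) == n_rows
        assert set(table.columns) >= {"axis", "value", "accuracy_mean",
                                      "f1_mean", "accuracy_std", "f1_std"}

    def test_unknown_axis_rejected(self, tiny_setup):
        dataset, config = tiny_setup
        with pytest.raises(ValueError):
            run_ablation("optimizer", config, SMALL_BACKBONE, dataset,
                         ImputationPolicy())
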