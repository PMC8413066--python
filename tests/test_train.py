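"""Training protocol, metrics, evaluation drivers and BN adaptation."""

import dataclasses

import numpy as np
import pytest

from hvpnet.model import HvpnConfig, build_model
from hvpnet.nn import BatchNorm
from hvpnet.train import (EvalResult, TrainConfig, accuracy, adabn_adapt,
                          intrasubject_eval, losocv_eval, lr_schedule,
                          majority_vote, pretrain_then_finetune, train)

from conftest import TINY_MODEL


def small_cfg(G=3, C=4, dims=(8, 7), variant="hvpn", **kw):
    return HvpnConfig(view_dims=dims, channels=C, num_classes=G,
                      variant=variant, **{**TINY_MODEL, **kw})


def separable_views(rng, cfg, n_per_class=12):
    """Linearly separable multiview data: class-dependent mean shifts."""
    G = cfg.num_classes
    labels = np.repeat(np.arange(G), n_per_class)
    views = []
    for m in cfg.view_dims:
        shift = rng.standard_normal((G, m, cfg.channels)) * 3.0
        x = rng.standard_normal((G * n_per_class, m, cfg.channels))
        views.append(x + shift[labels])
    return views, labels


class TestLrSchedule:
    def test_benchmark_schedule_values(self):
        cfg = TrainConfig()  # 28 epochs, drops after 16 and 24
        assert lr_schedule(0, cfg) == 0.1
        assert lr_schedule(15, cfg) == 0.1
        assert lr_schedule(16, cfg) == pytest.approx(0.01)
        assert lr_schedule(23, cfg) == pytest.approx(0.01)
        assert lr_schedule(24, cfg) == pytest.approx(0.001)
        assert lr_schedule(27, cfg) == pytest.approx(0.001)

    def test_monotone_non_increasing(self):
        cfg = TrainConfig()
        rates = [lr_schedule(e, cfg) for e in range(cfg.epochs)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_out_of_range_epochs_rejected(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            lr_schedule(-1, cfg)
        with pytest.raises(ValueError):
            lr_schedule(28, cfg)

    def test_invalid_drop_schedule_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, lr_drops=(8, 3))
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, lr_drops=(10,))


class TestMetrics:
    def test_accuracy_closed_form(self):
        assert accuracy(np.array([1, 2, 3, 4]), np.array([1, 2, 3, 0])) == 75.0
        assert accuracy(np.array([1, 1]), np.array([1, 1])) == 100.0

    def test_accuracy_matches_loop_count(self, rng):
        p = rng.integers(0, 5, 200)
        y = rng.integers(0, 5, 200)
        loop = 100.0 * sum(int(a == b) for a, b in zip(p, y)) / 200
        assert accuracy(p, y) == pytest.approx(loop)

    def test_accuracy_errors(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            accuracy(np.array([1]), np.array([1, 2]))

    def test_majority_vote(self, rng):
        assert majority_vote([2, 2, 5]) == 2
        assert majority_vote([1, 3]) == 1  # tie -> lowest class
        with pytest.raises(ValueError):
            majority_vote([])
        for _ in range(20):
            votes = rng.integers(0, 4, rng.integers(1, 15))
            counts = {v: (votes == v).sum() for v in set(votes.tolist())}
            best = min(v for v, c in counts.items()
                       if c == max(counts.values()))
            assert majority_vote(votes) == best

    def test_eval_result_mean_and_bounds(self):
        r = EvalResult({1: 80.0, 2: 90.0})
        assert r.mean_accuracy == 85.0
        with pytest.raises(ValueError):
            EvalResult({1: 120.0})
        with pytest.raises(ValueError):
            EvalResult({})


class TestTrain:
    def test_loss_decreases_on_separable_data(self, rng):
        cfg = small_cfg(G=4)
        m = build_model(cfg, seed=0)
        views, labels = separable_views(rng, cfg)
        tc = TrainConfig(epochs=10, batch_size=16, lr_init=0.05,
                         lr_drops=(8,), dropout=0.0, seed=0)
        trace = train(m, views, labels, tc)
        assert trace[-1] < trace[0]

    def test_seeded_training_is_bitwise_reproducible(self, rng):
        cfg = small_cfg()
        views, labels = separable_views(rng, cfg, n_per_class=6)
        tc = TrainConfig(epochs=2, batch_size=8, lr_init=0.05, lr_drops=(),
                         seed=42)
        weights = []
        for _ in range(2):
            m = build_model(cfg, seed=1)
            train(m, views, labels, tc)
            weights.append({k: v.copy() for k, v in m.state_dict().items()})
        for k in weights[0]:
            np.testing.assert_array_equal(weights[0][k], weights[1][k])

    def test_empty_training_set_rejected(self):
        cfg = small_cfg()
        m = build_model(cfg)
        with pytest.raises(ValueError, match="empty"):
            train(m, [np.zeros((0, 8, 4)), np.zeros((0, 7, 4))],
                  np.zeros(0, dtype=int), TrainConfig())

    def test_out_of_range_labels_rejected(self, rng):
        cfg = small_cfg(G=3)
        m = build_model(cfg)
        views, labels = separable_views(rng, cfg, n_per_class=2)
        with pytest.raises(ValueError, match="labels"):
            train(m, views, labels + 5,
                  TrainConfig(epochs=1, lr_drops=(), batch_size=4))

    def test_summed_score_loss_mode_trains(self, rng):
        cfg = small_cfg(G=3)
        m = build_model(cfg, seed=0)
        views, labels = separable_views(rng, cfg)
        tc = TrainConfig(epochs=6, batch_size=16, lr_init=0.05, lr_drops=(),
                         dropout=0.0, seed=0, loss_mode="summed_score")
        trace = train(m, views, labels, tc)
        assert trace[-1] < trace[0]


class TestPretrainFinetune:
    def test_subject_models_start_from_pretrained_weights(self, rng):
        cfg = small_cfg()
        views, labels = separable_views(rng, cfg, n_per_class=6)
        zero_epochs = TrainConfig(epochs=0, lr_drops=())
        pre_cfg = TrainConfig(epochs=1, batch_size=8, lr_init=0.01,
                              lr_drops=(), seed=0)
        pre, models = pretrain_then_finetune(
            (views, labels), {7: (views, labels)}, cfg,
            pre_cfg, zero_epochs)
        pre_state = pre.state_dict()
        sub_state = models[7].state_dict()
        for k in pre_state:
            np.testing.assert_array_equal(pre_state[k], sub_state[k])

    def test_default_dropout_rates(self, rng):
        from hvpnet.nn import Dropout
        cfg = small_cfg()
        views, labels = separable_views(rng, cfg, n_per_class=4)
        tc = TrainConfig(epochs=1, batch_size=8, lr_init=0.01, lr_drops=())
        pre, models = pretrain_then_finetune(
            (views, labels), {0: (views, labels)}, cfg, tc, tc)
        # pretraining leaves the model at 0.5, finetuning at 0.65
        assert all(d.p == 0.5 for d in pre.modules()
                   if isinstance(d, Dropout))
        assert all(d.p == 0.65 for d in models[0].modules()
                   if isinstance(d, Dropout))


class TestAdaBN:
    def _trained_toy(self, rng, cfg=None):
        cfg = cfg or small_cfg()
        m = build_model(cfg, seed=2)
        views, labels = separable_views(rng, cfg, n_per_class=6)
        train(m, views, labels, TrainConfig(epochs=2, batch_size=8,
                                            lr_init=0.05, lr_drops=(),
                                            seed=0))
        return m, cfg

    def test_learnable_weights_bitwise_unchanged(self, rng):
        m, cfg = self._trained_toy(rng)
        calib = [rng.standard_normal((20, d, cfg.channels)) * 2.0
                 for d in cfg.view_dims]
        adapted = adabn_adapt(m, calib)
        for (ka, pa), (kb, pb) in zip(sorted(m.named_parameters()),
                                      sorted(adapted.named_parameters())):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_input_bn_stats_equal_calibration_moments(self, rng):
        m, cfg = self._trained_toy(rng)
        calib = [rng.standard_normal((30, d, cfg.channels)) + 1.5
                 for d in cfg.view_dims]
        adapted = adabn_adapt(m, calib, batch_size=8)
        for j, branch in enumerate(adapted.branches):
            np.testing.assert_allclose(branch.in_bn.running_mean,
                                       calib[j].mean(axis=(0, 2)), atol=1e-5)
            np.testing.assert_allclose(branch.in_bn.running_var,
                                       calib[j].var(axis=(0, 2)), atol=1e-5)

    def test_adaptation_is_idempotent(self, rng):
        m, cfg = self._trained_toy(rng)
        calib = [rng.standard_normal((16, d, cfg.channels))
                 for d in cfg.view_dims]
        once = adabn_adapt(m, calib, batch_size=8)
        twice = adabn_adapt(once, calib, batch_size=8)
        for a, b in zip((x for x in once.modules()
                         if isinstance(x, BatchNorm)),
                        (x for x in twice.modules()
                         if isinstance(x, BatchNorm))):
            np.testing.assert_allclose(a.running_mean, b.running_mean,
                                       atol=1e-12)
            np.testing.assert_allclose(a.running_var, b.running_var,
                                       atol=1e-12)

    def test_empty_calibration_rejected(self, rng):
        m, cfg = self._trained_toy(rng)
        with pytest.raises(ValueError, match="empty"):
            adabn_adapt(m, [np.zeros((0, d, cfg.channels))
                            for d in cfg.view_dims])


FAST_TRAIN = dict(epochs=2, batch_size=32, lr_init=0.05, lr_drops=(),
                  dropout=0.1)


class TestEvalDrivers:
    def test_intrasubject_respects_trial_split(self, tiny_dataset):
        spec, recs, pspec = tiny_dataset
        res = intrasubject_eval(recs, pspec,
                                TrainConfig(seed=0, **FAST_TRAIN),
                                model_kwargs=TINY_MODEL,
                                view_ids=(1, 2), window_ms=200,
                                increment_ms=100)
        assert set(res.per_unit_accuracy) == {0, 1}
        assert res.mean_accuracy == pytest.approx(
            np.mean(list(res.per_unit_accuracy.values())))
        for sid in (0, 1):  # windows that fed gradients came from {1,3} only
            assert set(res.extras["train_trial_ids"][sid]) <= {1, 3}
            assert set(res.extras["test_trial_ids"][sid]) == {2}

    def test_voting_is_per_trial(self, tiny_dataset):
        spec, recs, pspec = tiny_dataset
        res = intrasubject_eval(recs, pspec,
                                TrainConfig(seed=0, **FAST_TRAIN),
                                model_kwargs=TINY_MODEL, view_ids=(1, 2),
                                window_ms=200, increment_ms=100)
        # one test trial x 3 gestures per subject -> voting acc is a
        # multiple of 100/3
        for v in res.voting_per_unit.values():
            assert v == pytest.approx(round(v / (100 / 3)) * (100 / 3))

    def test_losocv_folds_exclude_held_out_subject(self, tiny_dataset):
        spec, recs, pspec = tiny_dataset
        res = losocv_eval(recs, pspec, TrainConfig(seed=0, **FAST_TRAIN),
                          model_kwargs=TINY_MODEL, view_ids=(1, 2),
                          window_ms=200, increment_ms=100)
        assert set(res.per_unit_accuracy) == {0, 1}
        for held_out, trained_on in res.extras["fold_train_subjects"].items():
            assert held_out not in trained_on
            assert set(trained_on) == {0, 1} - {held_out}

    def test_losocv_requires_two_subjects(self, tiny_dataset):
        spec, recs, pspec = tiny_dataset
        with pytest.raises(ValueError, match="2 subjects"):
            losocv_eval(recs[:1], pspec)

    def test_seeded_run_is_reproducible(self, tiny_dataset):
        spec, recs, pspec = tiny_dataset
        kw = dict(train_cfg=TrainConfig(seed=5, **FAST_TRAIN),
                  model_kwargs=TINY_MODEL, view_ids=(1, 2),
                  window_ms=200, increment_ms=100)
        a = intrasubject_eval(recs, pspec, **kw)
        b = intrasubject_eval(recs, pspec, **kw)
        assert a.per_unit_accuracy == b.per_unit_accuracy
        assert a.voting_per_unit == b.voting_per_unit
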