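"""Losses and the progressive training loop."""

import numpy as np
import pytest

import progseg as ps
from progseg.model import ModelConfig, build_model
from progseg.nn import RMSProp, Tensor
from progseg.training import (
    TrainConfig,
    bce_loss,
    composite_loss,
    evaluate_loss,
    fit,
    soft_dice_loss,
    train_epoch,
    train_patient_pass,
)


class TestSoftDice:
    def test_perfect_binary_prediction_scores_zero(self):
        t = (np.random.default_rng(0).uniform(size=(2, 6, 6, 6)) > 0.5).astype(float)
        assert soft_dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_prediction_scores_one(self):
        t = np.zeros((1, 6, 6, 6))
        t[0, :3] = 1.0
        assert soft_dice_loss(1.0 - t, t).item() == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_prediction_closed_form(self):
        """p=0.5 everywhere, target half-filled: 1 - (2*0.25N)/(0.5N+0.5N) = 0.5."""
        t = np.zeros((1, 8, 8, 8))
        t[0, :4] = 1.0
        p = np.full_like(t, 0.5)
        assert soft_dice_loss(p, t).item() == pytest.approx(0.5, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((1, 4, 4, 4)), np.zeros((2, 4, 4, 4)))


class TestCompositeLoss:
    def test_uniform_half_prediction_bce_is_log_two(self):
        t = (np.random.default_rng(1).uniform(size=(2, 5, 5, 5)) > 0.5).astype(float)
        p = np.full_like(t, 0.5)
        assert bce_loss(p, t).item() == pytest.approx(np.log(2.0), abs=1e-12)

    def test_perfect_prediction_is_near_zero(self):
        t = (np.random.default_rng(2).uniform(size=(1, 5, 5, 5)) > 0.5).astype(float)
        p = np.clip(t, 1e-7, 1 - 1e-7)
        assert composite_loss(p, t).item() == pytest.approx(0.0, abs=1e-5)

    def test_equal_weight_decomposition_holds_exactly(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.99, size=(3, 6, 6, 6))
        t = (rng.uniform(size=p.shape) > 0.5).astype(float)
        total = composite_loss(p, t).item()
        parts = 0.5 * bce_loss(p, t).item() + 0.5 * soft_dice_loss(p, t).item()
        assert total == pytest.approx(parts, abs=1e-9)

    def test_matches_scalar_loop_oracle(self):
        """Brute-force elementwise BCE + per-channel Dice on a tiny volume."""
        rng = np.random.default_rng(4)
        p = rng.uniform(0.05, 0.95, size=(2, 3, 3, 3))
        t = (rng.uniform(size=p.shape) > 0.5).astype(float)
        bce_terms = []
        for c in np.ndindex(p.shape):
            bce_terms.append(-(t[c] * np.log(p[c]) + (1 - t[c]) * np.log(1 - p[c])))
        dice_terms = []
        for ch in range(2):
            inter = float((p[ch] * t[ch]).sum())
            denom = float(p[ch].sum() + t[ch].sum())
            dice_terms.append(1 - (2 * inter + 1e-6) / (denom + 1e-6))
        expect = 0.5 * np.mean(bce_terms) + 0.5 * np.mean(dice_terms)
        assert composite_loss(p, t).item() == pytest.approx(expect, abs=1e-9)

    def test_loss_is_differentiable(self):
        rng = np.random.default_rng(5)
        p = Tensor(rng.uniform(0.1, 0.9, size=(1, 4, 4, 4)), requires_grad=True)
        t = (rng.uniform(size=(1, 4, 4, 4)) > 0.5).astype(float)
        composite_loss(p, t).backward()
        assert p.grad is not None and np.all(np.isfinite(p.grad))


def small_model(seed=1, out=2):
    return build_model(ModelConfig(in_channels=3, out_channels=out,
                                   base_features=2, levels=2, seed=seed))


@pytest.fixture(scope="module")
def cohort():
    pcfg = ps.PhantomConfig(shape=(8, 8, 8), n_structures=1, dvf_amplitude=1.0,
                            dvf_smoothness=2.0)
    return ps.build_pretrain_cohort(4, pcfg, scales=(0.0, 1.0), seed=9)


@pytest.fixture(scope="module")
def one_patient():
    pcfg = ps.PhantomConfig(shape=(8, 8, 8), n_structures=1, dvf_amplitude=1.0,
                            dvf_smoothness=2.0)
    return ps.build_pretrain_cohort(1, pcfg, scales=(-1.0, 1.0), seed=2)


class TestTrainPatientPass:
    def test_memory_zeroed_after_pass(self, tiny_series):
        model = small_model()
        cfg = TrainConfig(learning_rate=1e-4, seed=0)
        opt = RMSProp(model.parameters(), lr=cfg.learning_rate)
        train_patient_pass(model, tiny_series, opt, cfg)
        assert model.memory is not None
        for h, c in model.memory:
            assert not np.any(h)
            assert not np.any(c)

    def test_one_loss_entry_per_fraction(self, tiny_series):
        model = small_model()
        cfg = TrainConfig(learning_rate=1e-4, seed=0)
        opt = RMSProp(model.parameters(), lr=cfg.learning_rate)
        losses = train_patient_pass(model, tiny_series, opt, cfg)
        assert len(losses) == tiny_series.n_fractions

    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_series):
        model = small_model()
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(learning_rate=0.0, min_learning_rate=0.0, seed=0)
        opt = RMSProp(model.parameters(), lr=0.0)
        train_patient_pass(model, tiny_series, opt, cfg)
        after = model.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_through_time_backprop_takes_one_step_per_patient(self, tiny_series):
        model = small_model()
        cfg = TrainConfig(learning_rate=1e-4, seed=0, detach_memory=False)
        opt = RMSProp(model.parameters(), lr=cfg.learning_rate)
        losses = train_patient_pass(model, tiny_series, opt, cfg)
        assert len(losses) == tiny_series.n_fractions
        assert np.all(np.isfinite(losses))


class TestTrainEpoch:
    def test_each_patient_visited_exactly_once(self, cohort):
        model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
        cfg = TrainConfig(learning_rate=1e-4, seed=0)
        opt = RMSProp(model.parameters(), lr=cfg.learning_rate)
        frag = train_epoch(model, cohort, opt, cfg, epoch=0)
        assert sorted(frag["order"]) == sorted(s.patient_id for s in cohort)

    def test_permutations_differ_across_epochs(self, cohort):
        model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
        cfg = TrainConfig(learning_rate=0.0, min_learning_rate=0.0, seed=0)
        opt = RMSProp(model.parameters(), lr=0.0)
        orders = [tuple(train_epoch(model, cohort, opt, cfg, epoch=e)["order"])
                  for e in range(6)]
        assert len(set(orders)) > 1

    def test_fixed_seed_reproduces_visit_order(self, cohort):
        cfg = TrainConfig(learning_rate=0.0, min_learning_rate=0.0, seed=5)
        orders = []
        for _ in range(2):
            model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
            opt = RMSProp(model.parameters(), lr=0.0)
            orders.append(tuple(train_epoch(model, cohort, opt, cfg, epoch=3)["order"]))
        assert orders[0] == orders[1]


class TestFit:
    def test_epoch_count_and_lr_trajectory(self, one_patient):
        model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
        cfg = TrainConfig(learning_rate=1e-4, pretrain_epochs=6, plateau_patience=1,
                          seed=0)
        log = fit(model, one_patient, config=cfg)
        assert len(log.epochs) == 6
        lrs = log.lr_trajectory
        assert all(b <= a + 1e-18 for a, b in zip(lrs, lrs[1:]))  # never increases
        assert min(lrs) >= cfg.min_learning_rate

    def test_lr_floor_reached_under_forced_plateau(self):
        """A flat monitored loss drives the rate from 1e-5 down to exactly
        the 1e-8 floor and no further."""
        from progseg.nn import ReduceLROnPlateau, RMSProp, Tensor
        opt = RMSProp([Tensor(np.zeros(1), requires_grad=True)], lr=1e-5)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=3, min_lr=1e-8)
        for _ in range(40):
            sched.step(1.0)
        assert opt.lr == pytest.approx(1e-8)

    def test_training_reduces_loss_on_tiny_problem(self, one_patient):
        model = build_model(ModelConfig(3, 1, 4, 2, seed=1))
        cfg = TrainConfig(learning_rate=2e-3, pretrain_epochs=8, seed=3)
        log = fit(model, one_patient, config=cfg)
        assert log.epochs[-1]["train_loss"] < log.epochs[0]["train_loss"]

    def test_two_runs_with_same_seed_are_identical(self, one_patient):
        losses = []
        for _ in range(2):
            model = build_model(ModelConfig(3, 1, 2, 2, seed=4))
            cfg = TrainConfig(learning_rate=1e-3, pretrain_epochs=3, seed=8)
            log = fit(model, one_patient, config=cfg)
            losses.append([e["train_loss"] for e in log.epochs])
        assert losses[0] == losses[1]

    def test_finetune_phase_runs_from_pretrained_state(self, one_patient):
        model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
        cfg = TrainConfig(learning_rate=1e-3, pretrain_epochs=2, finetune_epochs=2, seed=0)
        log = fit(model, one_patient, finetune_cohort=one_patient, config=cfg)
        phases = [e["phase"] for e in log.epochs]
        assert phases == ["pretrain"] * 2 + ["finetune"] * 2

    def test_log_dataframe_has_loss_columns(self, one_patient):
        model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
        cfg = TrainConfig(learning_rate=1e-3, pretrain_epochs=2, seed=0)
        df = fit(model, one_patient, config=cfg).to_dataframe()
        assert {"phase", "epoch", "lr", "train_loss", "val_loss"} <= set(df.columns)

    def test_gradient_clipping_bounds_global_norm(self):
        from progseg.training import clip_grad_norm

        rng = np.random.default_rng(0)
        params = [Tensor(rng.normal(size=(4, 4)), requires_grad=True) for _ in range(3)]
        for p in params:
            p.grad = rng.normal(size=p.data.shape) * 10.0
        before = clip_grad_norm(params, 1.0)
        assert before > 1.0
        after = np.sqrt(sum((p.grad ** 2).sum() for p in params))
        assert after == pytest.approx(1.0, rel=1e-9)

    def test_training_state_roundtrip_resumes_exactly(self, one_patient, tmp_path):
        """Model + optimizer (+ scheduler) survive a save/load cycle."""
        from progseg.nn import ReduceLROnPlateau
        from progseg.training import load_training_state, save_training_state

        model = small_model(seed=2, out=1)
        cfg = TrainConfig(learning_rate=1e-3, seed=0)
        opt = RMSProp(model.parameters(), lr=cfg.learning_rate)
        sched = ReduceLROnPlateau(opt, min_lr=cfg.min_learning_rate)
        train_patient_pass(model, one_patient[0], opt, cfg)
        sched.step(0.5)
        save_training_state(tmp_path / "state.npz", model, opt, sched)

        model2 = small_model(seed=9, out=1)
        opt2 = RMSProp(model2.parameters(), lr=1.0)
        sched2 = ReduceLROnPlateau(opt2, min_lr=0.0)
        load_training_state(tmp_path / "state.npz", model2, opt2, sched2)
        assert opt2.lr == opt.lr
        assert sched2.best == sched.best
        for a, b in zip(opt.square_avg, opt2.square_avg):
            assert np.array_equal(a, b)
        losses1 = train_patient_pass(model, one_patient[0], opt, cfg)
        losses2 = train_patient_pass(model2, one_patient[0], opt2, cfg)
        assert losses1 == losses2  # resumed run is bit-identical

    def test_evaluate_loss_is_finite_and_stateless(self, one_patient):
        model = build_model(ModelConfig(3, 1, 2, 2, seed=0))
        cfg = TrainConfig(seed=0)
        a = evaluate_loss(model, one_patient, cfg)
        b = evaluate_loss(model, one_patient, cfg)
        assert np.isfinite(a) and a == b
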