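"""Architecture and ConvLSTM cell behaviour."""

import numpy as np
import pytest
from scipy import ndimage

import progseg as ps
from progseg import nn
from progseg.model import (
    ConvLSTMCell,
    ModelConfig,
    build_model,
    count_parameters,
    load_checkpoint,
    load_memory,
    save_checkpoint,
    save_memory,
)
from progseg.nn import Tensor
from progseg.training import composite_loss


def zero_biases(module):
    for name, p in module.named_parameters().items():
        leaf = name.rsplit(".", 1)[-1]
        if leaf.startswith("b") or leaf == "beta":
            p.data[...] = 0.0


class TestConvLSTMCell:
    def test_zero_input_zero_state_zero_bias_is_fixed_point(self):
        cell = ConvLSTMCell(2, np.random.default_rng(0))
        zero_biases(cell)
        z = Tensor(np.zeros((2, 4, 4, 4)))
        h, c = cell(z, z, z)
        assert not np.any(h.data)
        assert not np.any(c.data)

    def test_forget_gate_halves_cell_state_at_zero_preactivation(self):
        """x=0, h=0, zero biases: f = sigmoid(0) = 1/2, i.g = 0, so c = C/2."""
        cell = ConvLSTMCell(2, np.random.default_rng(0))
        zero_biases(cell)
        z = Tensor(np.zeros((2, 4, 4, 4)))
        C = Tensor(np.random.default_rng(1).normal(size=(2, 4, 4, 4)))
        _, c = cell(z, z, C)
        assert np.allclose(c.data, 0.5 * C.data, atol=1e-12)

    def test_cell_matches_elementwise_gate_oracle(self):
        """Independent oracle: the six gate equations computed directly with
        scipy correlation, per channel, on a random 4^3 input."""
        rng = np.random.default_rng(7)
        ch = 2
        cell = ConvLSTMCell(ch, rng)
        x = rng.normal(size=(ch, 4, 4, 4))
        h0 = rng.normal(size=(ch, 4, 4, 4))
        c0 = rng.normal(size=(ch, 4, 4, 4))
        h, c = cell(Tensor(x), Tensor(h0), Tensor(c0))

        def oracle_conv(inp, w):
            out = np.zeros((ch,) + inp.shape[1:])
            for o in range(ch):
                for i in range(ch):
                    out[o] += ndimage.correlate(inp[i], w[o, i], mode="constant")
            return out

        def gate(name):
            wx = getattr(cell, f"wx_{name}").data
            wh = getattr(cell, f"wh_{name}").data
            b = getattr(cell, f"b_{name}").data.reshape(-1, 1, 1, 1)
            return oracle_conv(x, wx) + oracle_conv(h0, wh) + b

        sig = lambda v: 1 / (1 + np.exp(-v))
        i, f, o = sig(gate("i")), sig(gate("f")), sig(gate("o"))
        g = np.tanh(gate("g"))
        c_ref = f * c0 + i * g
        h_ref = o * np.tanh(c_ref)
        assert np.allclose(c.data, c_ref, atol=1e-6)
        assert np.allclose(h.data, h_ref, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        cell = ConvLSTMCell(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            cell(Tensor(np.zeros((2, 4, 4, 4))), Tensor(np.zeros((2, 8, 8, 8))),
                 Tensor(np.zeros((2, 4, 4, 4))))


class TestMemory:
    def test_init_memory_all_zero_with_one_pair_per_level(self, tiny_config):
        model = build_model(tiny_config)
        mem = model.init_memory((8, 8, 8))
        assert len(mem) == tiny_config.levels
        for h, c in mem:
            assert not np.any(h)
            assert not np.any(c)

    def test_memory_shapes_follow_channel_doubling_rule(self):
        cfg = ModelConfig(in_channels=3, out_channels=2, base_features=4, levels=3, seed=0)
        mem = build_model(cfg).init_memory((16, 16, 16))
        for level, (h, c) in enumerate(mem, start=1):
            expect = (4 * 2 ** (level - 1),) + tuple(16 // 2 ** (level - 1) for _ in range(3))
            assert h.shape == expect
            assert c.shape == expect

    def test_indivisible_spatial_shape_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            build_model(tiny_config).init_memory((9, 8, 8))

    def test_zero_bias_zero_input_forward_keeps_memory_at_zero(self, tiny_config):
        model = build_model(tiny_config)
        zero_biases(model)
        x = np.zeros((3, 8, 8, 8))
        _, mem = model.predict(x)
        for h, c in mem:
            assert not np.any(h)
            assert not np.any(c)

    def test_memory_roundtrips_through_disk(self, tiny_config, tmp_path):
        model = build_model(tiny_config)
        rng = np.random.default_rng(0)
        _, mem = model.predict(rng.uniform(size=(3, 8, 8, 8)))
        save_memory(mem, tmp_path / "mem.npz")
        back = load_memory(tmp_path / "mem.npz")
        for (h, c), (h2, c2) in zip(mem, back):
            assert np.array_equal(h, h2)
            assert np.array_equal(c, c2)


class TestForward:
    def test_probabilities_in_unit_interval(self, tiny_config):
        model = build_model(tiny_config)
        x = np.random.default_rng(0).uniform(size=(3, 8, 8, 8))
        probs, _ = model.predict(x)
        assert probs.shape == (2, 8, 8, 8)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_identical_input_and_memory_is_deterministic(self, tiny_config):
        model = build_model(tiny_config)
        x = np.random.default_rng(1).uniform(size=(3, 8, 8, 8))
        p1, _ = model.predict(x)
        p2, _ = model.predict(x)
        assert np.array_equal(p1, p2)

    def test_sequential_calls_update_memory(self, tiny_config):
        model = build_model(tiny_config)
        x = np.random.default_rng(2).uniform(size=(3, 8, 8, 8))
        _, mem1 = model.predict(x)
        _, mem2 = model.predict(x, mem1)
        assert any(not np.array_equal(c1, c2)
                   for (_, c1), (_, c2) in zip(mem1, mem2))

    def test_resolution_contract_of_encoder_levels(self):
        cfg = ModelConfig(in_channels=3, out_channels=1, base_features=2, levels=3, seed=0)
        mem = build_model(cfg).init_memory((16, 16, 16))
        assert [h.shape[1:] for h, _ in mem] == [(16,) * 3, (8,) * 3, (4,) * 3]

    def test_wrong_channel_count_rejected(self, tiny_config):
        model = build_model(tiny_config)
        with pytest.raises(ValueError):
            model(np.zeros((1, 8, 8, 8)))

    def test_skip_source_switch_changes_output(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(3, 8, 8, 8))
        pc = build_model(ModelConfig(3, 1, 2, 2, seed=5, skip_source="c"))
        ph = build_model(ModelConfig(3, 1, 2, 2, seed=5, skip_source="h"))
        a, mem = pc.predict(x)
        a2, _ = pc.predict(x, mem)  # nonzero memory: c and h paths diverge
        b, memh = ph.predict(x)
        b2, _ = ph.predict(x, memh)
        assert not np.array_equal(a2, b2)


class TestBaselines:
    def test_unet_ds_takes_single_channel_only(self):
        model = build_model(ModelConfig(1, 2, 2, 2, variant="unet_ds", seed=0))
        probs, mem = model.predict(np.zeros((1, 8, 8, 8)))
        assert mem is None
        with pytest.raises(ValueError):
            model(np.zeros((3, 8, 8, 8)))
        with pytest.raises(ValueError):
            ModelConfig(3, 2, 2, 2, variant="unet_ds")

    def test_baselines_are_stateless_and_deterministic(self):
        model = build_model(ModelConfig(3, 2, 2, 2, variant="unet_prior", seed=0))
        x = np.random.default_rng(0).uniform(size=(3, 8, 8, 8))
        p1, _ = model.predict(x)
        p2, _ = model.predict(x)
        assert np.array_equal(p1, p2)

    def test_prior_baseline_has_more_parameters_than_ds(self):
        prior = ModelConfig(3, 2, 4, 3, variant="unet_prior", seed=0)
        ds = ModelConfig(1, 2, 4, 3, variant="unet_ds", seed=0)
        assert count_parameters(prior) > count_parameters(ds)


class TestParameterCounts:
    def test_lstm_variant_is_strict_superset_of_ds(self):
        lstm = ModelConfig(3, 2, 4, 3, variant="lstm_unet", seed=0)
        ds = ModelConfig(1, 2, 4, 3, variant="unet_ds", seed=0)
        assert count_parameters(lstm) > count_parameters(ds)

    def test_doubling_features_roughly_quadruples_count(self):
        small = ModelConfig(3, 2, 4, 3, seed=0)
        big = ModelConfig(3, 2, 8, 3, seed=0)
        ratio = count_parameters(big) / count_parameters(small)
        assert 3.0 < ratio < 4.5  # conv weights dominate; input convs dilute

    def test_count_independent_of_input_volume(self, tiny_config):
        model = build_model(tiny_config)
        n = count_parameters(model)
        model.predict(np.zeros((3, 8, 8, 8)))
        model.predict(np.zeros((3, 16, 16, 16)))
        assert count_parameters(model) == n


class TestGradientFlow:
    def test_every_parameter_receives_gradient(self, tiny_config):
        """With backprop through time across three fractions, every kernel of
        every gate at every level contributes to the accumulated composite
        loss.  The output gate reaches the loss only via h(t)'s use at the
        *next* fraction, because the decoder consumes c(t); its
        hidden-to-gate kernel additionally needs a nonzero carried h, i.e. a
        three-fraction chain.  Both paths require the un-truncated graph."""
        model = build_model(tiny_config)
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(3, 8, 8, 8))
        target = (rng.uniform(size=(2, 8, 8, 8)) > 0.5).astype(float)
        mem, loss = None, None
        for _ in range(3):  # keep the graph: no detachment between fractions
            probs, mem = model(x, mem)
            term = composite_loss(probs, target)
            loss = term if loss is None else loss + term
        loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.any(p.grad != 0), f"{name} gradient identically zero"


class TestCheckpoint:
    def test_checkpoint_roundtrip_preserves_predictions(self, tiny_config, tmp_path):
        model = build_model(tiny_config)
        x = np.random.default_rng(5).uniform(size=(3, 8, 8, 8))
        p1, _ = model.predict(x)
        save_checkpoint(model, tmp_path / "ckpt.npz", extra={"note": "test"})
        model2, extra = load_checkpoint(tmp_path / "ckpt.npz")
        assert extra["note"] == "test"
        assert model2.config == tiny_config
        p2, _ = model2.predict(x)
        assert np.array_equal(p1, p2)
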