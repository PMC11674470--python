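"""Hybrid attention network: geometry, attention oracle, causality,
permutation consistency, checkpoints."""

import dataclasses

import numpy as np
import pytest

from somnastage import nn
from somnastage.model import (CausalQKV, FeatureOptimizer, ModelConfig,
                              MultiBranchExtractor, SEResidualBlock,
                              attention_weights, build_model,
                              load_checkpoint, multi_head_attention,
                              save_checkpoint)


def dense_attention_oracle(q, k, v, d_heads, scale="d"):
    """Brute-force multi-head scaled dot-product attention (pure numpy
    loops; independent of the Tensor implementation)."""
    n, p, width = q.shape
    dk = width // d_heads
    s = d_heads if scale == "d" else np.sqrt(dk)
    out = np.zeros_like(q)
    for b in range(n):
        for h in range(d_heads):
            sl = slice(h * dk, (h + 1) * dk)
            qh, kh, vh = q[b, :, sl], k[b, :, sl], v[b, :, sl]
            for i in range(p):
                z = np.array([qh[i] @ kh[j] / s for j in range(p)])
                z = np.exp(z - z.max())
                a = z / z.sum()
                out[b, i, sl] = sum(a[j] * vh[j] for j in range(p))
    return out


class TestAttention:
    def test_matches_dense_oracle(self, rng):
        q, k, v = (rng.normal(size=(2, 6, 10)).astype(np.float32)
                   for _ in range(3))
        for scale in ("d", "sqrt_dk"):
            got = multi_head_attention(q, k, v, d_heads=5, scale=scale).data
            want = dense_attention_oracle(q, k, v, 5, scale)
            assert np.abs(got - want).max() < 1e-6

    def test_single_head_equals_direct_formula(self, rng):
        q, k, v = (rng.normal(size=(1, 4, 3)).astype(np.float32)
                   for _ in range(3))
        got = multi_head_attention(q, k, v, d_heads=1).data
        want = dense_attention_oracle(q, k, v, 1)
        assert np.abs(got - want).max() < 1e-6

    def test_rows_are_probability_vectors(self, rng):
        for _ in range(50):
            q = rng.normal(size=(1, 6, 10)).astype(np.float32)
            k = rng.normal(size=(1, 6, 10)).astype(np.float32)
            a = attention_weights(q, k, d_heads=5)
            assert np.all(a >= 0)
            assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)

    def test_sequence_length_one_returns_value(self, rng):
        q, k, v = (rng.normal(size=(1, 1, 10)).astype(np.float32)
                   for _ in range(3))
        out = multi_head_attention(q, k, v, d_heads=5).data
        assert np.allclose(out, v, atol=1e-6)

    def test_indivisible_width_rejected(self, rng):
        q = rng.normal(size=(1, 4, 9)).astype(np.float32)
        with pytest.raises(ValueError, match="divisible"):
            multi_head_attention(q, q, q, d_heads=5)


class TestExtractor:
    def test_concatenated_time_width_is_80(self):
        cfg = ModelConfig()
        assert cfg.extractor_width == 80
        rng = np.random.default_rng(0)
        ext = MultiBranchExtractor(cfg, rng)
        ext.eval()
        out = ext(nn.Tensor(np.random.default_rng(1).normal(
            size=(2, 1, 3000)).astype(np.float32)))
        assert out.data.shape == (2, 128, 80)

    def test_zero_input_zero_bias_gives_zero_output(self):
        cfg = ModelConfig()
        ext = MultiBranchExtractor(cfg, np.random.default_rng(0))
        ext.eval()
        for branch in (ext.branch_a, ext.branch_b):
            branch.conv1.bias.data[:] = 0
            branch.conv2.bias.data[:] = 0
        out = ext(nn.Tensor(np.zeros((1, 1, 3000), dtype=np.float32)))
        assert np.allclose(out.data, 0)

    def test_eval_mode_deterministic(self, rng):
        ext = MultiBranchExtractor(ModelConfig(), np.random.default_rng(0))
        ext.eval()
        x = nn.Tensor(rng.normal(size=(1, 1, 3000)).astype(np.float32))
        assert np.array_equal(ext(x).data, ext(x).data)

    def test_wrong_length_rejected(self):
        ext = MultiBranchExtractor(ModelConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            ext(nn.Tensor(np.zeros((1, 1, 2999), dtype=np.float32)))


class TestSEBlock:
    def test_gate_values_in_unit_interval(self, rng):
        blk = SEResidualBlock(128, ModelConfig(), np.random.default_rng(0))
        for _ in range(10):
            h = nn.Tensor(rng.normal(size=(2, 30, 80)).astype(np.float32))
            g = blk.gate(h).data
            assert np.all((g > 0) & (g < 1))

    def test_gate_symmetric_under_channel_exchange(self, rng):
        # with channel-symmetric excitation weights, identical input
        # channels receive identical gates
        blk = SEResidualBlock(128, ModelConfig(), np.random.default_rng(0))
        blk.fc_excite.weight.data[:] = blk.fc_excite.weight.data[:, :1]
        blk.fc_excite.bias.data[:] = 0.3
        row = rng.normal(size=(1, 1, 80)).astype(np.float32)
        h = nn.Tensor(np.repeat(row, 30, axis=1))
        g = blk.gate(h).data
        assert np.allclose(g, g[:, :1], atol=1e-7)

    def test_output_shape_preserved_across_repeats(self, rng):
        cfg = ModelConfig()
        b1 = SEResidualBlock(128, cfg, np.random.default_rng(0))
        b2 = SEResidualBlock(30, cfg, np.random.default_rng(1))
        x = nn.Tensor(rng.normal(size=(2, 128, 80)).astype(np.float32))
        out = b2(b1(x))
        assert out.data.shape == (2, 30, 80)


class TestCausality:
    def test_qkv_future_perturbation_leaves_past_unchanged(self, rng):
        qkv = CausalQKV(ModelConfig(), np.random.default_rng(0))
        x = rng.normal(size=(1, 30, 80)).astype(np.float32)
        base = [t.data.copy() for t in qkv(nn.Tensor(x))]
        x2 = x.copy()
        x2[:, :, -1] += 10.0   # perturb only the last time step
        pert = [t.data for t in qkv(nn.Tensor(x2))]
        for b, p in zip(base, pert):
            assert np.array_equal(b[:, :, :-1], p[:, :, :-1])

    def test_zero_input_zero_bias_gives_zero_qkv(self):
        qkv = CausalQKV(ModelConfig(), np.random.default_rng(0))
        for conv in (qkv.q_conv, qkv.k_conv, qkv.v_conv):
            conv.bias.data[:] = 0
        out = qkv(nn.Tensor(np.zeros((1, 30, 80), dtype=np.float32)))
        for t in out:
            assert np.allclose(t.data, 0)

    def test_receptive_field_at_most_7_past_steps(self, rng):
        qkv = CausalQKV(ModelConfig(), np.random.default_rng(0))
        x = rng.normal(size=(1, 30, 80)).astype(np.float32)
        base = qkv(nn.Tensor(x))[0].data
        t = 40
        x2 = x.copy()
        x2[:, :, t] += 5.0
        pert = qkv(nn.Tensor(x2))[0].data
        changed = np.where(np.any(base != pert, axis=(0, 1)))[0]
        assert changed.min() >= t
        assert changed.max() <= t + 6  # kernel size 7 -> t..t+6 affected

    def test_causality_through_stacked_qkv_convs(self, rng):
        # two causal layers in sequence stay causal (receptive field grows
        # but never looks ahead)
        cfg = ModelConfig()
        a = CausalQKV(cfg, np.random.default_rng(0))
        b = CausalQKV(cfg, np.random.default_rng(1))
        x = rng.normal(size=(1, 30, 80)).astype(np.float32)

        def stack(arr):
            q1, _, _ = a(nn.Tensor(arr))
            q2, _, _ = b(q1)
            return q2.data

        base = stack(x)
        x2 = x.copy()
        x2[:, :, 50:] += 3.0
        pert = stack(x2)
        assert np.array_equal(base[:, :, :50], pert[:, :, :50])


class TestModel:
    def test_forward_shape_and_probabilities(self, rng):
        model = build_model(ModelConfig(n_channels=2, n_classes=4, seed=0))
        x = rng.normal(size=(3, 2, 3000)).astype(np.float32)
        proba = model.predict_proba(x)
        assert proba.shape == (3, 4)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_three_towers_have_unshared_parameters(self):
        model = build_model(ModelConfig(n_channels=3, n_classes=5, seed=0))
        assert len(model.towers) == 3
        w0 = model.towers[0].extract.branch_a.conv1.weight.data
        w1 = model.towers[1].extract.branch_a.conv1.weight.data
        assert not np.array_equal(w0, w1)

    def test_ablated_model_has_fewer_parameters(self):
        full = build_model(ModelConfig(n_channels=2, n_classes=5))
        ablated = build_model(ModelConfig(n_channels=2, n_classes=5,
                                          feature_optimization=False))
        assert ablated.n_parameters() < full.n_parameters()
        assert all(t.optimizer is None for t in ablated.towers)

    def test_fused_width_scales_with_channel_count(self):
        m1 = build_model(ModelConfig(n_channels=1, n_classes=5))
        m3 = build_model(ModelConfig(n_channels=3, n_classes=5))
        assert m3.fc_fuse.weight.data.shape[0] == \
            3 * m1.fc_fuse.weight.data.shape[0]

    def test_permutation_consistency(self, rng):
        """Permuting channels together with tower assignment and the fusion
        weight blocks leaves the output unchanged."""
        model = build_model(ModelConfig(n_channels=3, n_classes=5, seed=0))
        model.eval()
        x = rng.normal(size=(2, 3, 3000)).astype(np.float32)
        base = model.predict_proba(x)
        perm = [2, 0, 1]
        model.towers = [model.towers[i] for i in perm]
        width = model.towers[0].out_width
        blocks = [model.fc_fuse.weight.data[i * width:(i + 1) * width]
                  for i in range(3)]
        model.fc_fuse.weight.data = np.concatenate([blocks[i] for i in perm])
        out = model.predict_proba(x[:, perm, :])
        assert np.allclose(out, base, atol=1e-5)

    def test_inconsistent_tower_shapes_rejected(self, rng):
        model = build_model(ModelConfig(n_channels=2, n_classes=5))
        a = nn.Tensor(rng.normal(size=(2, 30, 80)).astype(np.float32))
        b = nn.Tensor(rng.normal(size=(2, 30, 79)).astype(np.float32))
        with pytest.raises(ValueError, match="inconsistent"):
            model.fuse_and_classify([a, b])

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_model(ModelConfig(n_channels=1, n_classes=3, seed=4))
        model.eval()
        x = rng.normal(size=(2, 1, 3000)).astype(np.float32)
        before = model.predict_proba(x)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        assert back.config == model.config
        assert np.allclose(back.predict_proba(x), before, atol=1e-6)

    def test_branch2_stride_5_geometry_rejected_by_ff(self):
        # as printed, a long-branch stride of 5 cannot cohere with the
        # 80-unit feed-forward; the config surfaces this immediately
        b2 = dataclasses.replace(ModelConfig().branch2, stride=5)
        with pytest.raises(ValueError):
            build_model(dataclasses.replace(ModelConfig(), branch2=b2))
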