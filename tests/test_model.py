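"""Classifier architecture contracts: layer stack shapes, attentive
statistics pooling against brute-force weighted moments, SE and frequency
gating behavior, ablation toggles and gradient flow."""
import numpy as np
import pytest

from copdscreen.nn import (AttentiveStatsPooling, ECAPAClassifier, FreqGate,
                           ModelConfig, SEBlock, Tensor, build_model)

RNG = np.random.default_rng(0)


def small_config(**kw):
    base = dict(channels=16, embedding_dim=16, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestArchitecture:
    def test_default_config_output_shapes(self):
        model = build_model(ModelConfig(seed=0))  # full size: 1024 ch, 192 emb
        out = model.forward(RNG.normal(size=(3, 80, 120)).astype(np.float32))
        assert out.logits.shape == (3, 2)
        assert out.embedding.shape == (3, 192)

    def test_variable_length_inputs_same_embedding_dim(self):
        model = build_model(small_config())
        e1 = model.forward(RNG.normal(size=(2, 80, 100))).embedding
        e2 = model.forward(RNG.normal(size=(2, 80, 300))).embedding
        assert e1.shape == e2.shape == (2, 16)

    def test_same_seed_identical_initial_parameters(self):
        a = build_model(small_config(seed=7))
        b = build_model(small_config(seed=7))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_eval_mode_deterministic_logits(self):
        model = build_model(small_config())
        model.eval()
        x = RNG.normal(size=(2, 80, 60)).astype(np.float32)
        l1 = model.forward(x).logits.data
        l2 = model.forward(x).logits.data
        assert np.array_equal(l1, l2)

    def test_wrong_input_shape_rejected(self):
        model = build_model(small_config())
        with pytest.raises(ValueError, match="expected input"):
            model.forward(np.zeros((2, 40, 10), dtype=np.float32))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(channels=0)
        with pytest.raises(ValueError):
            ModelConfig(dropout_p=1.5)
        with pytest.raises(ValueError):
            ModelConfig(pooling="max")

    def test_seres2_variant_forward_and_shapes(self):
        model = build_model(small_config(block_style="SERes2"))
        out = model.forward(RNG.normal(size=(2, 80, 64)))
        assert out.logits.shape == (2, 2)
        loss, _ = model.loss(RNG.normal(size=(2, 80, 64)).astype(np.float32),
                             np.array([0, 1]))
        loss.backward()

    def test_gradient_reaches_every_parameter(self):
        # se_reduction=4 keeps the SE bottleneck wide enough that no unit
        # is dead at init on a small random batch
        model = build_model(small_config(freq_gate=True, se_reduction=4))
        loss, _ = model.loss(RNG.normal(size=(4, 80, 32)).astype(np.float32),
                             np.array([0, 1, 1, 0]))
        model.zero_grad()
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.any(p.grad != 0)


class TestCheckpoint:
    def test_roundtrip_preserves_eval_outputs(self, tmp_path):
        from copdscreen.nn import AdamW, load_checkpoint, save_checkpoint
        model = build_model(small_config(seed=3))
        x = RNG.normal(size=(4, 80, 20)).astype(np.float32)
        loss, _ = model.loss(x, np.array([0, 1, 0, 1]))
        loss.backward()
        opt = AdamW(model.parameters())
        opt.step()  # move away from init so running stats/weights are nontrivial
        model.eval()
        ref = model.forward(x).logits.data
        path = save_checkpoint(model, str(tmp_path / "ckpt.npz"))
        restored = load_checkpoint(path)
        assert restored.config == model.config
        assert np.array_equal(restored.forward(x).logits.data, ref)

    def test_state_dict_restores_batchnorm_buffers(self):
        model = build_model(small_config(seed=4))
        x = RNG.normal(size=(4, 80, 20)).astype(np.float32)
        model.loss(x, np.array([0, 1, 0, 1]))  # train-mode pass updates stats
        state = model.state_dict()
        saved = model.stage1.bn.running_mean.copy()
        model.stage1.bn.running_mean[:] = 123.0
        model.load_state_dict(state)
        assert np.array_equal(model.stage1.bn.running_mean, saved)


class TestAttentiveStatsPooling:
    def _hp(self, C=8, T=20, seed=1):
        rng = np.random.default_rng(seed)
        return AttentiveStatsPooling(C, rng), Tensor(
            rng.normal(size=(2, C, T)).astype(np.float32))

    def test_attention_normalized_and_nonnegative(self):
        pool, h = self._hp()
        _, alpha = pool(h)
        assert np.all(alpha.data >= 0)
        assert np.allclose(alpha.data.sum(axis=2), 1.0, atol=1e-5)

    def test_uniform_weights_reduce_to_frame_mean(self):
        pool, h = self._hp()
        T = h.shape[2]
        alpha = Tensor(np.full((2, 1, T), 1.0 / T, dtype=np.float32))
        pooled, _ = pool(h, alpha)
        mu = pooled.data[:, :8]
        assert np.allclose(mu, h.data.mean(axis=2), atol=1e-6)

    def test_one_hot_weights_give_selected_frame_and_zero_std(self):
        pool, h = self._hp()
        alpha = np.zeros((2, 1, 20), dtype=np.float32)
        alpha[:, :, 5] = 1.0
        pooled, _ = pool(h, Tensor(alpha))
        assert np.allclose(pooled.data[:, :8], h.data[:, :, 5], atol=1e-6)
        assert np.allclose(pooled.data[:, 8:], 0.0, atol=1e-4)

    def test_moments_match_bruteforce_oracle(self):
        pool, h = self._hp(C=8, T=20, seed=4)
        rng = np.random.default_rng(9)
        a = rng.random((2, 1, 20)).astype(np.float32)
        a /= a.sum(axis=2, keepdims=True)
        pooled, _ = pool(h, Tensor(a))
        mu_ref = (h.data * a).sum(axis=2)
        var_ref = ((h.data - mu_ref[:, :, None]) ** 2 * a).sum(axis=2)
        assert np.allclose(pooled.data[:, :8], mu_ref, atol=1e-6)
        assert np.allclose(pooled.data[:, 8:], np.sqrt(var_ref), atol=1e-5)

    def test_sigma_nonnegative_on_forward(self):
        pool, h = self._hp(seed=12)
        pooled, _ = pool(h)
        assert np.all(pooled.data[:, 8:] >= 0)


class TestGlobalAvgPool:
    def test_constant_frames_return_constant(self):
        model = build_model(small_config(pooling="GlobalAvg"))
        h = Tensor(np.full((1, 4, 10), 3.0, dtype=np.float32))
        pooled, alpha = model.pool(h)
        assert alpha is None
        assert np.allclose(pooled.data, 3.0)

    def test_equals_asp_mu_under_uniform_attention(self):
        rng = np.random.default_rng(2)
        h = Tensor(rng.normal(size=(2, 8, 15)).astype(np.float32))
        asp = AttentiveStatsPooling(8, rng)
        uniform = Tensor(np.full((2, 1, 15), 1 / 15, dtype=np.float32))
        pooled, _ = asp(h, uniform)
        assert np.allclose(pooled.data[:, :8], h.data.mean(axis=2), atol=1e-6)

    def test_matches_direct_mean_oracle(self):
        from copdscreen.nn import GlobalAvgPooling
        h = Tensor(RNG.normal(size=(3, 6, 11)).astype(np.float32))
        pooled, _ = GlobalAvgPooling()(h)
        assert np.allclose(pooled.data, h.data.mean(axis=2), atol=1e-7)


class TestSEBlock:
    def test_zero_input_zero_output(self):
        se = SEBlock(8, np.random.default_rng(0))
        out = se(Tensor(np.zeros((2, 8, 10), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_gates_strictly_inside_unit_interval(self):
        se = SEBlock(8, np.random.default_rng(1))
        g = se.gates(Tensor(RNG.normal(size=(4, 8, 10)).astype(np.float32)))
        assert np.all(g.data > 0) and np.all(g.data < 1)

    def test_channel_ratio_constant_along_time(self):
        se = SEBlock(8, np.random.default_rng(2))
        x = Tensor(RNG.normal(size=(2, 8, 10)).astype(np.float32) + 5.0)
        out = se(x)
        ratio = out.data / x.data
        assert np.allclose(ratio, ratio[:, :, :1], atol=1e-6)


class TestFreqGate:
    def test_identity_at_initialization(self):
        gate = FreqGate(80)
        x = Tensor(RNG.normal(size=(2, 80, 30)).astype(np.float32))
        out = gate(x)
        rel = np.abs(out.data - x.data) / (np.abs(x.data) + 1e-12)
        assert rel.max() < 1e-6

    def test_disabled_flag_exact_identity(self):
        model = build_model(small_config(freq_gate=False))
        assert model.freq_gate is None

    def test_per_band_ratio_constant_across_time_and_batch(self):
        gate = FreqGate(80)
        gate.logit.data = np.random.default_rng(3).normal(size=80).astype(np.float32)
        x = Tensor(RNG.normal(size=(3, 80, 20)).astype(np.float32) + 2.0)
        out = gate(x)
        ratio = out.data / x.data
        assert np.allclose(ratio, ratio[:1, :, :1], atol=1e-6)


class TestAblationToggles:
    def test_no_asp_is_pure_pooling_swap(self):
        full = small_config().to_dict()
        ablated = small_config(pooling="GlobalAvg").to_dict()
        diff = {k for k in full if full[k] != ablated[k]}
        assert diff == {"pooling"}

    def test_no_se_is_pure_flag_swap(self):
        full = small_config().to_dict()
        ablated = small_config(se_enabled=False).to_dict()
        diff = {k for k in full if full[k] != ablated[k]}
        assert diff == {"se_enabled"}

    def test_no_se_model_has_fewer_parameters(self):
        n_full = sum(p.data.size for p in build_model(small_config()).parameters())
        n_ablated = sum(p.data.size
                        for p in build_model(small_config(se_enabled=False)).parameters())
        assert n_ablated < n_full
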