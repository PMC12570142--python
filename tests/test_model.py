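"""Model mathematics: positional encoding, attention, loss, schedule,
parameter accounting, causality, and finite-difference gradient checks."""

import math

import numpy as np
import pytest

from smilesclm import (ClmConfig, TransformerLM, causal_attention,
                       count_parameters, lr_schedule, masked_loss,
                       positional_encoding)
from smilesclm.model import _softmax, causal_mask


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding(8, 6)
        assert np.allclose(pe[0, 0::2], 0.0)
        assert np.allclose(pe[0, 1::2], 1.0)

    def test_matches_independent_formula(self):
        d, L = 10, 7
        pe = positional_encoding(L, d)
        for pos in range(L):
            for i in range(0, d, 2):
                angle = pos / (10000.0 ** (i / d))
                assert pe[pos, i] == pytest.approx(math.sin(angle), abs=1e-12)
                assert pe[pos, i + 1] == pytest.approx(math.cos(angle), abs=1e-12)

    def test_values_bounded(self):
        pe = positional_encoding(100, 32)
        assert np.all(np.abs(pe) <= 1.0)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            positional_encoding(0, 4)
        with pytest.raises(ValueError):
            positional_encoding(4, 0)


class TestCausalAttention:
    def test_first_position_sees_only_itself(self, rng):
        q, k, v = (rng.standard_normal((5, 4)) for _ in range(3))
        out = causal_attention(q, k, v, scale_dim=4)
        assert np.allclose(out[0], v[0], atol=1e-12)

    def test_uniform_scores_average_allowed_values(self):
        t, d = 4, 3
        q = np.zeros((t, d))
        k = np.zeros((t, d))
        v = np.arange(t * d, dtype=float).reshape(t, d)
        out = causal_attention(q, k, v, scale_dim=d)
        for pos in range(t):
            assert np.allclose(out[pos], v[: pos + 1].mean(0), atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        t, d = 6, 4
        q, k, v = (rng.standard_normal((t, d)) for _ in range(3))
        out = causal_attention(q, k, v, scale_dim=d)
        for i in range(t):
            scores = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(i + 1)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            expect = sum(w[j] * v[j] for j in range(i + 1))
            assert np.allclose(out[i], expect, atol=1e-10)

    def test_future_values_irrelevant(self, rng):
        t, d = 5, 4
        q, k, v = (rng.standard_normal((t, d)) for _ in range(3))
        out = causal_attention(q, k, v, scale_dim=d)
        k2, v2 = k.copy(), v.copy()
        k2[-1] += 100.0
        v2[-1] -= 50.0
        out2 = causal_attention(q, k2, v2, scale_dim=d)
        assert np.allclose(out[:-1], out2[:-1], atol=1e-12)

    def test_weights_exactly_zero_beyond_frontier(self):
        m = causal_mask(4)
        w = _softmax(np.zeros((4, 4)) + m, axis=-1)
        w = np.where(m < 0, 0.0, w)
        assert np.all(w[np.triu_indices(4, k=1)] == 0.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            causal_attention(rng.standard_normal((3, 4)),
                             rng.standard_normal((3, 5)),
                             rng.standard_normal((3, 5)), scale_dim=4)


class TestMaskedLoss:
    def test_uniform_scores_give_log_vocab(self):
        v = 10
        scores = np.zeros((2, 5, v))
        targets = np.zeros((2, 5), dtype=int)
        mask = np.ones((2, 5))
        assert masked_loss(scores, targets, mask) == pytest.approx(math.log(v), abs=1e-12)

    def test_padding_excluded(self, rng):
        scores = rng.standard_normal((1, 6, 5))
        targets = rng.integers(0, 5, size=(1, 6))
        mask = np.array([[1, 1, 1, 0, 0, 0]], dtype=float)
        base = masked_loss(scores, targets, mask)
        scores2 = scores.copy()
        scores2[0, 3:] += 100.0  # perturb only padded positions
        assert masked_loss(scores2, targets, mask) == pytest.approx(base, abs=1e-9)

    def test_all_padding_raises(self):
        with pytest.raises(ValueError):
            masked_loss(np.zeros((1, 3, 4)), np.zeros((1, 3), int), np.zeros((1, 3)))

    def test_perfect_prediction_near_zero(self):
        scores = np.full((1, 3, 4), -1e3)
        targets = np.array([[1, 2, 3]])
        for t_pos, tid in enumerate(targets[0]):
            scores[0, t_pos, tid] = 1e3
        assert masked_loss(scores, targets, np.ones((1, 3))) < 1e-6


class TestLrSchedule:
    def test_frozen_values(self):
        # d_model=100, warmup=4000: start / peak / 4x-warmup decay point
        assert lr_schedule(1, 100, 4000) == pytest.approx(3.9528e-7, rel=1e-4)
        assert lr_schedule(4000, 100, 4000) == pytest.approx(1.5811e-3, rel=1e-4)
        assert lr_schedule(16000, 100, 4000) == pytest.approx(7.9057e-4, rel=1e-4)

    def test_peak_at_warmup(self):
        vals = [lr_schedule(s, 100, 400) for s in range(1, 2001)]
        assert int(np.argmax(vals)) + 1 == 400

    def test_linear_warmup(self):
        assert lr_schedule(200, 100, 400) == pytest.approx(
            0.5 * lr_schedule(400, 100, 400), rel=1e-12)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            lr_schedule(0, 100, 400)
        with pytest.raises(ValueError):
            lr_schedule(1, 100, 0)


class TestParameterCount:
    def test_toy_config_hand_count(self):
        cfg = ClmConfig(vocab_size=10, max_len=8, d_model=4, n_layers=1,
                        n_heads=1, d_ffn=8, dropout=0.0,
                        head_dim_convention="split_dmodel")
        assert count_parameters(cfg) == 262

    def test_vocab_growth(self):
        # each extra vocab token adds d_model (embedding) + d_model + 1 (head)
        cfg = ClmConfig(vocab_size=20, max_len=8, d_model=4, n_layers=1,
                        n_heads=1, d_ffn=8, dropout=0.0,
                        head_dim_convention="split_dmodel")
        assert count_parameters(cfg) == 262 + 10 * (4 + 4 + 1)

    def test_matches_instantiated_model(self):
        cfg = ClmConfig(vocab_size=12, max_len=16, d_model=10, n_layers=2,
                        n_heads=2, d_ffn=20)
        assert TransformerLM(cfg, seed=0).n_parameters() == count_parameters(cfg)

    def test_split_convention_divisibility(self):
        with pytest.raises(ValueError):
            ClmConfig(vocab_size=10, d_model=10, n_heads=4,
                      head_dim_convention="split_dmodel")


class TestTransformerLM:
    def test_output_shape(self, tiny_model):
        ids = np.array([[1, 3, 4, 2]])
        logits = tiny_model.forward(ids)
        assert logits.shape == (1, 4, tiny_model.config.vocab_size)
        assert np.all(np.isfinite(logits))

    def test_causality(self, tiny_model):
        ids = np.array([[1, 3, 4, 5, 2]])
        base = tiny_model.forward(ids)
        ids2 = ids.copy()
        ids2[0, -1] = 6  # change only the last token
        pert = tiny_model.forward(ids2)
        assert np.allclose(base[0, :-1], pert[0, :-1], atol=1e-6)

    def test_pad_extension_invariance(self, tiny_model):
        short = np.array([[1, 3, 4]])
        long = np.array([[1, 3, 4, 0, 0]])
        a = tiny_model.forward(short)
        b = tiny_model.forward(long)
        assert np.allclose(a[0], b[0, :3], atol=1e-6)

    def test_too_long_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.ones((1, tiny_model.config.max_len + 1), dtype=int))

    def test_bad_token_id(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.array([[tiny_model.config.vocab_size]]))

    def test_deterministic_init(self):
        cfg = ClmConfig(vocab_size=8, max_len=8, d_model=6, n_layers=1,
                        n_heads=1, d_ffn=12)
        a = TransformerLM(cfg, seed=4)
        b = TransformerLM(cfg, seed=4)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_dropout_only_with_rng_and_train(self, tiny_model, rng):
        tiny_model.config.dropout = 0.5
        ids = np.array([[1, 3, 4, 2]])
        a = tiny_model.forward(ids, train=False)
        b = tiny_model.forward(ids, train=False)
        assert np.array_equal(a, b)
        c = tiny_model.forward(ids, train=True, rng=rng)
        d = tiny_model.forward(ids, train=True, rng=rng)
        assert not np.array_equal(c, d)

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        p = tmp_path / "model.npz"
        tiny_model.save(p)
        loaded = TransformerLM.load(p)
        assert loaded.config == tiny_model.config
        ids = np.array([[1, 3, 4, 2]])
        assert np.allclose(loaded.forward(ids), tiny_model.forward(ids), atol=0)


class TestGradients:
    def test_finite_difference(self):
        cfg = ClmConfig(vocab_size=7, max_len=8, d_model=6, n_layers=2,
                        n_heads=2, d_ffn=10, dropout=0.0)
        model = TransformerLM(cfg, seed=1, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.integers(1, 7, size=(2, 5))
        y = rng.integers(1, 7, size=(2, 5))
        m = np.array([[1, 1, 1, 1, 0], [1, 1, 0, 0, 0]], dtype=float)
        _, grads = model.loss_and_grad(x, y, m, train=False)
        eps = 1e-6
        check_rng = np.random.default_rng(9)
        for name in ("embed", "l0.Wq", "l0.Wo", "l1.W1", "l1.ln2_g", "Wout", "l0.bv"):
            p = model.params[name]
            flat = p.reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = model.loss_and_grad(x, y, m, train=False)
                flat[idx] = orig - eps
                lm, _ = model.loss_and_grad(x, y, m, train=False)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[idx]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), name

    def test_gradient_keys_cover_all_params(self, tiny_model):
        x = np.array([[1, 3, 4, 2]])
        y = np.array([[3, 4, 2, 0]])
        m = np.array([[1, 1, 1, 0]], dtype=float)
        _, grads = tiny_model.loss_and_grad(x, y, m, train=False)
        assert set(grads) == set(tiny_model.params)
        for k, g in grads.items():
            assert g.shape == tiny_model.params[k].shape, k
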