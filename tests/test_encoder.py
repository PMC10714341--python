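"""Encode block correctness against loop-based oracles, plus stack properties."""

import numpy as np
import pytest

from m7gformer import autodiff as ad
from m7gformer.encoder import (EncoderConfig, LAYER_NORM_EPS, conv_sublayer,
                               encode, feedforward, init_block_params,
                               multi_head_attention, scaled_dot_attention)


def sdpa_oracle(Q, K, V):
    """Loop-based scaled dot-product attention."""
    n, d_k = Q.shape
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k)
                           for j in range(K.shape[0])])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        out[i] = sum(w[j] * V[j] for j in range(V.shape[0]))
    return out


def mha_oracle(X, p):
    """Per-head loop + concatenation + output projection."""
    h, d_k = p.n_heads, p.d_k
    heads = []
    for i in range(h):
        sl = slice(i * d_k, (i + 1) * d_k)
        heads.append(sdpa_oracle(X @ p.wq.data[:, sl], X @ p.wk.data[:, sl],
                                 X @ p.wv.data[:, sl]))
    return np.concatenate(heads, axis=1) @ p.wo.data


class TestScaledDotAttention:
    def test_single_row_returns_value_row(self):
        rng = np.random.default_rng(0)
        Q, K, V = rng.normal(size=(1, 4)), rng.normal(size=(1, 4)), \
            rng.normal(size=(1, 3))
        np.testing.assert_allclose(scaled_dot_attention(Q, K, V), V, atol=1e-12)

    def test_identical_keys_average_values(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(3, 4))
        K = np.tile(rng.normal(size=(1, 4)), (5, 1))
        V = rng.normal(size=(5, 2))
        out = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (3, 1)),
                                   atol=1e-9)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, m = rng.integers(1, 6, size=2)
            d_k, d_v = rng.integers(1, 5, size=2)
            Q = rng.normal(size=(n, d_k))
            K = rng.normal(size=(m, d_k))
            V = rng.normal(size=(m, d_v))
            np.testing.assert_allclose(scaled_dot_attention(Q, K, V),
                                       sdpa_oracle(Q, K, V), atol=1e-9)

    def test_softmax_rows_sum_to_one(self):
        from m7gformer.encoder import attention_weights
        rng = np.random.default_rng(3)
        for _ in range(20):
            W = attention_weights(rng.normal(size=(5, 4)),
                                  rng.normal(size=(7, 4)))
            np.testing.assert_allclose(W.sum(axis=-1), 1.0, atol=1e-6)
            assert np.all(W >= 0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)),
                                 np.zeros((2, 2)))
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((4, 3)),
                                 np.zeros((2, 2)))


class TestMultiHeadAttention:
    def test_matches_per_head_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = init_block_params(rng, d_model=6, n_heads=2, d_k=3,
                                  ffn_hidden=6).attn
            X = rng.normal(size=(5, 6))
            np.testing.assert_allclose(multi_head_attention(X, p),
                                       mha_oracle(X, p), atol=1e-9)

    def test_zero_output_projection_gives_zeros(self):
        rng = np.random.default_rng(5)
        p = init_block_params(rng).attn
        p.wo.data = np.zeros_like(p.wo.data)
        X = rng.normal(size=(43, 64))
        np.testing.assert_allclose(multi_head_attention(X, p), 0.0)

    def test_single_head_reduces_to_scaled_dot_attention(self):
        rng = np.random.default_rng(6)
        p = init_block_params(rng, d_model=2, n_heads=1, d_k=2,
                              ffn_hidden=2).attn
        X = rng.normal(size=(3, 2))
        expect = sdpa_oracle(X @ p.wq.data, X @ p.wk.data,
                             X @ p.wv.data) @ p.wo.data
        np.testing.assert_allclose(multi_head_attention(X, p), expect,
                                   atol=1e-12)


class TestConvSublayer:
    def test_identity_weights_pass_nonnegative_input(self):
        rng = np.random.default_rng(7)
        p = init_block_params(rng).conv
        p.W.data = np.eye(64)
        p.b.data = np.zeros(64)
        X = np.abs(rng.normal(size=(43, 64)))
        np.testing.assert_allclose(conv_sublayer(X, p), X)

    def test_relu_floor(self):
        rng = np.random.default_rng(8)
        p = init_block_params(rng).conv
        p.W.data = -np.eye(64)
        p.b.data = np.zeros(64)
        X = np.abs(rng.normal(size=(43, 64)))
        np.testing.assert_allclose(conv_sublayer(X, p), 0.0)

    def test_matches_positionwise_loop_oracle(self):
        rng = np.random.default_rng(9)
        p = init_block_params(rng, d_model=3).conv
        X = rng.normal(size=(4, 3))
        expect = np.array([np.maximum(p.W.data @ x + p.b.data, 0.0)
                           for x in X])
        got = conv_sublayer(X, p)
        np.testing.assert_allclose(got, expect, atol=1e-9)
        assert np.all(got >= 0)


class TestFeedforward:
    def test_zero_maps_give_zero(self):
        rng = np.random.default_rng(10)
        p = init_block_params(rng).ffn
        for t in (p.W1, p.b1, p.W2, p.b2):
            t.data = np.zeros_like(t.data)
        X = rng.normal(size=(43, 64))
        np.testing.assert_allclose(feedforward(X, p), 0.0)

    def test_matches_loop_oracle_and_preserves_shape(self):
        rng = np.random.default_rng(11)
        p = init_block_params(rng, d_model=4, ffn_hidden=5,
                              n_heads=1, d_k=4).ffn
        X = rng.normal(size=(6, 4))
        expect = np.array([
            np.maximum(x @ p.W1.data + p.b1.data, 0.0) @ p.W2.data + p.b2.data
            for x in X])
        got = feedforward(X, p)
        assert got.shape == X.shape
        np.testing.assert_allclose(got, expect, atol=1e-9)


class TestEncodeStack:
    def test_zero_sublayers_reduce_to_iterated_layernorm(self):
        """With all sublayer weights zero the block is LN∘LN∘LN of the input."""
        rng = np.random.default_rng(12)
        block = init_block_params(rng)
        for t in (block.attn.wo, block.conv.W, block.conv.b,
                  block.ffn.W2, block.ffn.b2):
            t.data = np.zeros_like(t.data)
        X = rng.normal(size=(43, 64))

        def ln(x):
            mu = x.mean(axis=-1, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
            return (x - mu) / np.sqrt(var + LAYER_NORM_EPS)

        got = encode(X, [block], EncoderConfig(n_blocks=1))
        np.testing.assert_allclose(got, ln(ln(ln(X))), atol=1e-9)

    def test_output_shape_preserved(self):
        rng = np.random.default_rng(13)
        blocks = [init_block_params(rng) for _ in range(3)]
        X = rng.normal(size=(43, 64))
        assert encode(X, blocks, EncoderConfig(n_blocks=3)).shape == (43, 64)

    def test_conv_ablation_changes_output(self):
        rng = np.random.default_rng(14)
        blocks = [init_block_params(rng)]
        X = rng.normal(size=(43, 64))
        with_conv = encode(X, blocks, EncoderConfig(n_blocks=1, use_conv=True))
        without = encode(X, blocks, EncoderConfig(n_blocks=1, use_conv=False))
        assert not np.allclose(with_conv, without)

    def test_block_count_validated(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):
            encode(np.zeros((4, 64)), [], EncoderConfig(n_blocks=1))
        with pytest.raises(ValueError):
            EncoderConfig(n_blocks=0)
        with pytest.raises(ValueError):
            encode(np.zeros((4, 64)), [init_block_params(rng)],
                   EncoderConfig(n_blocks=2))

    def test_eval_mode_is_deterministic(self):
        rng = np.random.default_rng(16)
        blocks = [init_block_params(rng) for _ in range(2)]
        X = rng.normal(size=(43, 64))
        a = encode(X, blocks, EncoderConfig(n_blocks=2))
        b = encode(X, blocks, EncoderConfig(n_blocks=2))
        assert np.array_equal(a, b)

    def test_permutation_equivariance_without_position_encoding(self):
        """Permuting interior rows permutes outputs identically: all sublayers
        are position-agnostic, so order information can only come from PE."""
        rng = np.random.default_rng(17)
        blocks = [init_block_params(rng) for _ in range(2)]
        cfg = EncoderConfig(n_blocks=2)
        X = rng.normal(size=(43, 64))
        perm = np.r_[0, 1 + rng.permutation(41), 42]
        out = encode(X, blocks, cfg)
        out_perm = encode(X[perm], blocks, cfg)
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)
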