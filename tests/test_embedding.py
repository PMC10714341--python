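"""Tokenization, coverage, soft-attention fusion and position encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m7gformer import autodiff as ad
from m7gformer.autodiff import Tensor
from m7gformer.embedding import (CoverageMap, EmbeddingParams,
                                 PositionEncodingConfig, SoftAttentionStage,
                                 TokenizerConfig, build_coverage,
                                 embed_sequence, embed_tokens,
                                 init_embedding_params, kmerize,
                                 position_encoding, soft_attention_fuse,
                                 vocabulary)
from m7gformer.sequence_io import RnaWindow, WINDOW_LENGTH


# -- k-mer tokenization ------------------------------------------------

def test_kmerize_worked_example():
    assert kmerize("CAGCU", 2).kmers == ["CA", "AG", "GC", "CU"]


@pytest.mark.parametrize("seq,k,expect", [
    ("CAGCU", 1, ["C", "A", "G", "C", "U"]),
    ("ACGU", 3, ["ACG", "CGU"]),
])
def test_kmerize_examples(seq, k, expect):
    assert kmerize(seq, k).kmers == expect


def test_kmerize_ids_are_lexicographic():
    view = kmerize("AACU", 2)
    vocab = vocabulary(2)
    assert [vocab[i] for i in view.token_ids] == view.kmers
    assert vocab == sorted(vocab)


def test_kmerize_rejects_oversized_k():
    with pytest.raises(ValueError):
        kmerize("ACG", 4)


@settings(max_examples=30, deadline=None)
@given(st.text(alphabet="ACGU", min_size=1, max_size=50), st.integers(1, 50))
def test_kmerize_token_count_property(seq, k):
    if k > len(seq):
        with pytest.raises(ValueError):
            kmerize(seq, k)
    else:
        view = kmerize(seq, k)
        assert len(view.kmers) == len(seq) - k + 1
        assert all(len(m) == k for m in view.kmers)


# -- coverage ----------------------------------------------------------

def test_coverage_interior_base_has_six_real_candidates():
    cov = build_coverage(WINDOW_LENGTH, TokenizerConfig())
    entries = cov.entries(20)
    assert len(entries) == 6
    assert all(slot != CoverageMap.PAD for _, slot in entries)
    # each referenced k-mer really contains the base
    for k, slot in entries:
        assert slot <= 20 <= slot + k - 1


def test_coverage_first_base_pads_out_of_range_slots():
    cov = build_coverage(WINDOW_LENGTH, TokenizerConfig())
    scale2 = [slot for k, slot in cov.entries(0) if k == 2]
    assert scale2 == [CoverageMap.PAD, 0]  # window starting at -1 is padded


def test_coverage_single_scale():
    cov = build_coverage(10, TokenizerConfig(scales=(1,)))
    assert all(len(cov.entries(p)) == 1 for p in range(10))


def test_tokenizer_config_validation():
    with pytest.raises(ValueError):
        TokenizerConfig(scales=())
    with pytest.raises(ValueError):
        TokenizerConfig(scales=(0,))
    with pytest.raises(ValueError):
        TokenizerConfig(scales=(1, 4))
    TokenizerConfig(scales=(1, 4), allow_large_k=True)  # explicit override


# -- soft attention fusion ---------------------------------------------

def _random_stage(rng, d=8):
    return SoftAttentionStage(
        W=Tensor(rng.normal(size=(d, d))),
        b=Tensor(rng.normal(size=d)),
        v=Tensor(rng.normal(size=d)),
    )


def test_fuse_identical_candidates_returns_that_vector():
    rng = np.random.default_rng(0)
    stage = _random_stage(rng)
    e = rng.normal(size=8)
    fused, w = soft_attention_fuse([e, e, e], stage)
    np.testing.assert_allclose(fused, e, atol=1e-12)
    np.testing.assert_allclose(w.sum(), 1.0, atol=1e-12)


def test_fuse_single_candidate_is_identity():
    rng = np.random.default_rng(1)
    stage = _random_stage(rng)
    e = rng.normal(size=8)
    fused, w = soft_attention_fuse([e], stage)
    np.testing.assert_allclose(fused, e)
    np.testing.assert_allclose(w, [1.0])


def test_fuse_weights_match_scalar_softmax_oracle():
    rng = np.random.default_rng(2)
    stage = _random_stage(rng)
    cands = rng.normal(size=(2, 8))
    # independent scalar evaluation of score_j = v . tanh(W e_j + b)
    scores = [float(stage.v.data @ np.tanh(stage.W.data @ e + stage.b.data))
              for e in cands]
    expect = np.exp(scores) / np.sum(np.exp(scores))
    _, w = soft_attention_fuse(cands, stage)
    np.testing.assert_allclose(w, expect, atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(1, 6), st.integers(0, 1000))
def test_fusion_is_convex_combination(m, seed):
    """Weights nonnegative, sum to 1, and reconstruct the fused vector."""
    rng = np.random.default_rng(seed)
    stage = _random_stage(rng)
    cands = rng.normal(size=(m, 8))
    fused, w = soft_attention_fuse(cands, stage)
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) <= 1e-6
    np.testing.assert_allclose(fused, w @ cands, atol=1e-6)


def test_fuse_empty_candidates_raises():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError):
        soft_attention_fuse(np.empty((0, 8)), _random_stage(rng))


# -- position encoding -------------------------------------------------

def pe_scalar(pos, j, b=1000.0, d=64):
    """Independent scalar evaluation of the sinusoidal formula."""
    i = j // 2
    angle = pos / (b ** (2 * i / d))
    return np.sin(angle) if j % 2 == 0 else np.cos(angle)


def test_position_encoding_matches_scalar_formula_everywhere():
    pe = position_encoding(PositionEncodingConfig())
    assert pe.shape == (43, 64)
    for pos in range(43):
        for j in range(64):
            assert abs(pe[pos, j] - pe_scalar(pos, j)) <= 1e-9
    assert np.all(np.abs(pe) <= 1.0)


def test_position_encoding_row_zero_alternates():
    pe = position_encoding(PositionEncodingConfig())
    np.testing.assert_allclose(pe[0, 0::2], 0.0)
    np.testing.assert_allclose(pe[0, 1::2], 1.0)
    assert abs(pe[1, 0] - np.sin(1.0)) <= 1e-12
    assert abs(pe[2, 1] - np.cos(2.0)) <= 1e-12


def test_position_encoding_rejects_odd_dimension():
    with pytest.raises(ValueError):
        PositionEncodingConfig(d_model=63)


# -- token embedding ---------------------------------------------------

def _window(seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), WINDOW_LENGTH))
    seq = seq[:20] + "G" + seq[21:]
    return RnaWindow("w", seq, 1)


def test_embed_tokens_shape_and_boundary_rows():
    params = init_embedding_params(rng=np.random.default_rng(0))
    mat = embed_tokens(_window(), params)
    assert mat.shape == (43, 64)
    np.testing.assert_allclose(mat[0], params.start.data)
    np.testing.assert_allclose(mat[-1], params.end.data)
    assert np.all(np.isfinite(mat))


def test_embed_tokens_constant_tables_give_constant_rows():
    """Convexity: identical candidates fuse to the shared constant vector."""
    params = init_embedding_params(rng=np.random.default_rng(1))
    c = np.linspace(-1, 1, 64)
    for key in params.tables:
        params.tables[key].data = np.tile(c, (params.tables[key].shape[0], 1))
    mat = embed_tokens(_window(), params)
    np.testing.assert_allclose(mat[1:-1], np.tile(c, (41, 1)), atol=1e-9)


def test_embed_tokens_matches_per_base_fusion_oracle():
    """Batch path equals explicit per-base two-stage soft_attention_fuse."""
    params = init_embedding_params(rng=np.random.default_rng(2))
    w = _window(5)
    cov = build_coverage(w.sequence, params.config)
    mat = embed_tokens(w, params, cov)
    from m7gformer.embedding import tokenize_ids
    ids = {k: tokenize_ids(w.sequence, k) for k in (1, 2, 3)}
    for p in (0, 7, 20, 40):
        sense_vecs = []
        for m in range(3):
            cands = []
            for k, slot in cov.entries(p):
                if slot == CoverageMap.PAD:
                    cands.append(params.tables[(k, m)].data[params.config.pad_id(k)])
                else:
                    cands.append(params.tables[(k, m)].data[ids[k][slot]])
            fused, _ = soft_attention_fuse(cands, params.scale_stage)
            sense_vecs.append(fused)
        expect, _ = soft_attention_fuse(sense_vecs, params.sense_stage)
        np.testing.assert_allclose(mat[p + 1], expect, atol=1e-9)


def test_embed_sequence_adds_position_encoding_elementwise():
    params = init_embedding_params(rng=np.random.default_rng(3))
    w = _window(6)
    tokens = embed_tokens(w, params)
    pe = position_encoding(PositionEncodingConfig())
    np.testing.assert_allclose(embed_sequence(w, params, pe), tokens + pe)
    with pytest.raises(ValueError):
        embed_sequence(w, params, pe[:10])
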