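"""Encode block: multi-head self-attention, size-1 convolution, feedforward.

Each block applies, in order, multi-head scaled dot-product attention, a
shape-preserving convolutional sublayer (64 size-1 filters, i.e. a
position-wise channel mix), and a two-layer position-wise feedforward
network; each sublayer is wrapped post-norm as ``LayerNorm(x + Sublayer(x))``.
The convolutional sublayer computes ``ReLU(Dropout(W x + b))`` per token
position and can be disabled for the "traditional encoder" ablation.

Public functions accept plain numpy arrays (returning numpy, eval mode) or
:class:`~m7gformer.autodiff.Tensor` (returning a Tensor on the training
graph); both run the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttentionParams",
    "ConvParams",
    "FfnParams",
    "EncoderBlockParams",
    "EncoderConfig",
    "scaled_dot_attention",
    "multi_head_attention",
    "conv_sublayer",
    "feedforward",
    "encode",
    "init_block_params",
]

LAYER_NORM_EPS = 1e-5


@dataclass
class AttentionParams:
    """Head projections stored stacked: wq/wk/wv (d_model, h*d_k), wo (h*d_k, d_model)."""

    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    n_heads: int
    d_k: int


@dataclass
class ConvParams:
    """One layer of d_model size-1 filters: channel-mix W (d, d) and bias b."""

    W: Tensor
    b: Tensor


@dataclass
class FfnParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor


@dataclass
class EncoderBlockParams:
    attn: AttentionParams
    conv: ConvParams
    ffn: FfnParams
    ln1_gain: Tensor
    ln1_shift: Tensor
    ln2_gain: Tensor
    ln2_shift: Tensor
    ln3_gain: Tensor
    ln3_shift: Tensor


@dataclass
class EncoderConfig:
    """Stack-level settings; conv/PE flags exist for the ablation variants."""

    n_blocks: int = 3
    dropout: float = 0.5
    use_conv: bool = True
    use_position_encoding: bool = True

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def _wrap(x):
    """(tensor, was_numpy) pair."""
    if isinstance(x, Tensor):
        return x, False
    return Tensor(x), True


def _unwrap(t: Tensor, was_numpy: bool):
    return t.data if was_numpy else t


def scaled_dot_attention(q, k, v):
    """softmax(Q K^T / sqrt(d_k)) V with the softmax over key positions."""
    q, nq = _wrap(q)
    k, _ = _wrap(k)
    v, _ = _wrap(v)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V must share the row count")
    d_k = q.shape[-1]
    scores = ad.matmul(q, ad.swapaxes(k, -1, -2)) / np.sqrt(d_k)
    weights = ad.softmax(scores, axis=-1)
    return _unwrap(ad.matmul(weights, v), nq)


def attention_weights(q, k) -> np.ndarray:
    """The softmax attention map alone (for inspection/tests)."""
    q, _ = _wrap(q)
    k, _ = _wrap(k)
    scores = ad.matmul(q, ad.swapaxes(k, -1, -2)) / np.sqrt(q.shape[-1])
    return ad.softmax(scores, axis=-1).data


def multi_head_attention(x, params: AttentionParams, dropout: float = 0.0,
                         training: bool = False,
                         rng: np.random.Generator | None = None):
    """Self-attention: per-head projections of x, attention, concat, W^O."""
    x, was_numpy = _wrap(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = ad.reshape(x, (1,) + x.shape)
    B, n, d_model = x.shape
    h, d_k = params.n_heads, params.d_k

    def heads(w):
        proj = ad.matmul(x, w)                       # (B, n, h*d_k)
        return ad.swapaxes(ad.reshape(proj, (B, n, h, d_k)), 1, 2)

    attended = scaled_dot_attention(heads(params.wq), heads(params.wk),
                                    heads(params.wv))     # (B, h, n, d_k)
    spliced = ad.reshape(ad.swapaxes(attended, 1, 2), (B, n, h * d_k))
    out = ad.matmul(spliced, params.wo)
    out = ad.dropout(out, dropout, rng, training)
    if squeeze:
        out = ad.reshape(out, (n, d_model))
    return _unwrap(out, was_numpy)


def conv_sublayer(x, params: ConvParams, training: bool = False,
                  rng: np.random.Generator | None = None,
                  dropout: float = 0.5):
    """Position-wise ReLU(Dropout(W x + b)); dropout active only in training."""
    x, was_numpy = _wrap(x)
    pre = ad.matmul(x, ad.swapaxes(params.W, 0, 1)) + params.b
    pre = ad.dropout(pre, dropout, rng, training)
    return _unwrap(ad.relu(pre), was_numpy)


def feedforward(x, params: FfnParams, dropout: float = 0.0,
                training: bool = False,
                rng: np.random.Generator | None = None):
    """Position-wise affine -> ReLU -> (dropout) -> affine."""
    x, was_numpy = _wrap(x)
    hidden = ad.relu(ad.matmul(x, params.W1) + params.b1)
    hidden = ad.dropout(hidden, dropout, rng, training)
    return _unwrap(ad.matmul(hidden, params.W2) + params.b2, was_numpy)


def encode(x, blocks: list[EncoderBlockParams], config: EncoderConfig,
           training: bool = False, rng: np.random.Generator | None = None):
    """Apply the full stack of encode blocks (attention -> conv -> FFN)."""
    if not blocks:
        raise ValueError("at least one encoder block is required")
    if len(blocks) != config.n_blocks:
        raise ValueError(f"got {len(blocks)} blocks, config says "
                         f"{config.n_blocks}")
    x, was_numpy = _wrap(x)
    for p in blocks:
        a = multi_head_attention(x, p.attn, config.dropout, training, rng)
        x = ad.layer_norm(x + a, p.ln1_gain, p.ln1_shift, LAYER_NORM_EPS)
        if config.use_conv:
            c = conv_sublayer(x, p.conv, training, rng, config.dropout)
            x = ad.layer_norm(x + c, p.ln2_gain, p.ln2_shift, LAYER_NORM_EPS)
        f = feedforward(x, p.ffn, config.dropout, training, rng)
        x = ad.layer_norm(x + f, p.ln3_gain, p.ln3_shift, LAYER_NORM_EPS)
    return _unwrap(x, was_numpy)


def init_block_params(rng: np.random.Generator, d_model: int = 64,
                      n_heads: int = 8, d_k: int = 32,
                      ffn_hidden: int = 64) -> EncoderBlockParams:
    """Seeded initialization: weights ~ N(0, 1/fan_in), zero biases, unit LN gain."""

    def lin(fan_in, fan_out):
        return Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                 size=(fan_in, fan_out)), requires_grad=True)

    attn = AttentionParams(
        wq=lin(d_model, n_heads * d_k),
        wk=lin(d_model, n_heads * d_k),
        wv=lin(d_model, n_heads * d_k),
        wo=lin(n_heads * d_k, d_model),
        n_heads=n_heads, d_k=d_k,
    )
    conv = ConvParams(W=lin(d_model, d_model),
                      b=Tensor(np.zeros(d_model), requires_grad=True))
    ffn = FfnParams(
        W1=lin(d_model, ffn_hidden),
        b1=Tensor(np.zeros(ffn_hidden), requires_grad=True),
        W2=lin(ffn_hidden, d_model),
        b2=Tensor(np.zeros(d_model), requires_grad=True),
    )

    def ln_pair():
        return (Tensor(np.ones(d_model), requires_grad=True),
                Tensor(np.zeros(d_model), requires_grad=True))

    ln1 = ln_pair()
    ln2 = ln_pair()
    ln3 = ln_pair()
    return EncoderBlockParams(attn=attn, conv=conv, ffn=ffn,
                              ln1_gain=ln1[0], ln1_shift=ln1[1],
                              ln2_gain=ln2[0], ln2_shift=ln2[1],
                              ln3_gain=ln3[0], ln3_shift=ln3[1])


def block_parameters(p: EncoderBlockParams) -> list[Tensor]:
    return [p.attn.wq, p.attn.wk, p.attn.wv, p.attn.wo,
            p.conv.W, p.conv.b,
            p.ffn.W1, p.ffn.b1, p.ffn.W2, p.ffn.b2,
            p.ln1_gain, p.ln1_shift, p.ln2_gain, p.ln2_shift,
            p.ln3_gain, p.ln3_shift]
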