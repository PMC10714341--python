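"""Output layer: pool the encoder output and produce class probabilities.

The 43 x 64 encoded matrix is reduced to one 64-vector (mean over the token
axis by default; the sequence-start boundary row is the alternative), then
passed through linear(64->16) -> ReLU -> dropout -> linear(16->2) -> softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["HeadParams", "Prediction", "pool", "classify", "init_head_params"]

POOL_MODES = ("mean", "boundary")


@dataclass
class HeadParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    pooling: str = "mean"
    dropout: float = 0.5


@dataclass
class Prediction:
    """Class probabilities and the thresholded label (p_pos >= 0.5 -> 1)."""

    p_pos: float
    p_neg: float

    @property
    def label(self) -> int:
        return int(self.p_pos >= 0.5)


def pool(encoded, mode: str = "mean"):
    """Reduce (..., n, d) to (..., d): column means or the first (boundary) row."""
    if mode not in POOL_MODES:
        raise ValueError(f"unknown pooling mode {mode!r}; choose from {POOL_MODES}")
    t = encoded if isinstance(encoded, Tensor) else Tensor(encoded)
    pooled = ad.tmean(t, axis=-2) if mode == "mean" else _first_row(t)
    return pooled if isinstance(encoded, Tensor) else pooled.data


def _first_row(t: Tensor) -> Tensor:
    n, d = t.shape[-2], t.shape[-1]
    picker = np.zeros((n, 1), dtype=t.data.dtype)
    picker[0, 0] = 1.0
    col = ad.matmul(ad.swapaxes(t, -1, -2), Tensor(picker))
    return ad.reshape(col, t.shape[:-2] + (d,))


def head_logits(pooled, params: HeadParams, training: bool = False,
                rng: np.random.Generator | None = None):
    """The two pre-softmax logits (Tensor path used during training)."""
    t = pooled if isinstance(pooled, Tensor) else Tensor(pooled)
    squeeze = t.ndim == 1
    if squeeze:
        t = ad.reshape(t, (1,) + t.shape)
    h = ad.relu(ad.matmul(t, params.W1) + params.b1)
    h = ad.dropout(h, params.dropout, rng, training)
    logits = ad.matmul(h, params.W2) + params.b2
    if squeeze:
        logits = ad.reshape(logits, (logits.shape[-1],))
    return logits


def classify(pooled, params: HeadParams, training: bool = False,
             rng: np.random.Generator | None = None) -> Prediction:
    """Class probabilities for one pooled 64-vector."""
    vec = np.asarray(pooled.data if isinstance(pooled, Tensor) else pooled,
                     dtype=np.float64)
    if vec.ndim != 1 or vec.shape[0] != params.W1.shape[0]:
        raise ValueError(f"expected a length-{params.W1.shape[0]} vector, "
                         f"got shape {vec.shape}")
    with ad.no_grad():
        logits = head_logits(Tensor(vec), params, training, rng)
        probs = ad.softmax(logits, axis=-1).data
    return Prediction(p_pos=float(probs[1]), p_neg=float(probs[0]))


def init_head_params(rng: np.random.Generator, d_model: int = 64,
                     hidden: int = 16, pooling: str = "mean",
                     dropout: float = 0.5) -> HeadParams:
    def lin(fan_in, fan_out):
        return Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                 size=(fan_in, fan_out)), requires_grad=True)

    return HeadParams(
        W1=lin(d_model, hidden),
        b1=Tensor(np.zeros(hidden), requires_grad=True),
        W2=lin(hidden, 2),
        b2=Tensor(np.zeros(2), requires_grad=True),
        pooling=pooling, dropout=dropout,
    )


def head_parameters(p: HeadParams) -> list[Tensor]:
    return [p.W1, p.b1, p.W2, p.b2]
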