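"""Multi-sense, multi-scale k-mer embedding with soft-attention fusion.

A 41-nt window is tokenised at several k-mer scales (k = 1, 2, 3 by
default).  At scale k, a base at position p is covered by up to k distinct
k-mers, so with scales {1,2,3} every base has six covering tokens (flank
positions are completed with per-scale pad tokens).  Each token carries
several alternative embedding vectors ("senses", 3 by default).  Two stages
of additive soft attention fuse, for each base, first the six scale
candidates within each sense and then the sense vectors, yielding one
64-vector per base.  Learned sequence-start/-end boundary vectors flank the
41 fused rows, giving the 43 x 64 token matrix, to which a fixed sinusoidal
position encoding is added elementwise.

The soft-attention scoring is the standard additive form
``score_j = v . tanh(W e_j + b)`` with weights ``softmax(scores)``, so each
fused vector is a convex combination of its candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sequence_io import ALPHABET, RnaWindow, WINDOW_LENGTH

__all__ = [
    "TokenizerConfig",
    "KmerView",
    "CoverageMap",
    "SoftAttentionStage",
    "EmbeddingParams",
    "PositionEncodingConfig",
    "kmerize",
    "tokenize_ids",
    "build_coverage",
    "soft_attention_fuse",
    "embed_tokens",
    "position_encoding",
    "embed_sequence",
    "init_embedding_params",
    "vocabulary",
    "export_vocabulary_tsv",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class TokenizerConfig:
    """k-mer scales and reserved symbols of the tokenizer.

    Pad and boundary symbols live outside every k-mer vocabulary: the pad
    token of scale k gets integer id 4**k, and the boundary (sequence-start /
    sequence-end) vectors are separate learned parameters, not vocabulary
    entries.
    """

    scales: tuple[int, ...] = (1, 2, 3)
    alphabet: str = ALPHABET
    pad_symbol: str = "<pad>"
    boundary_symbols: tuple[str, str] = ("<s>", "</s>")
    allow_large_k: bool = False

    def __post_init__(self):
        if not self.scales:
            raise ValueError("at least one k-mer scale is required")
        if any(k < 1 for k in self.scales):
            raise ValueError("k-mer scales must be >= 1")
        if max(self.scales) > 3 and not self.allow_large_k:
            raise ValueError("scales above 3 produce combinatorial "
                             "vocabularies; set allow_large_k to override")

    def vocab_size(self, k: int) -> int:
        """Vocabulary size at scale k, pad token included."""
        return len(self.alphabet) ** k + 1

    def pad_id(self, k: int) -> int:
        return len(self.alphabet) ** k

    @property
    def candidates_per_base(self) -> int:
        return sum(self.scales)


@dataclass
class KmerView:
    """Tokenisation of one sequence at one scale (stride-1 sliding window)."""

    scale: int
    kmers: list[str]
    token_ids: np.ndarray


def kmerize(sequence: str, k: int) -> KmerView:
    """Slide a width-k window over the sequence: the L-k+1 consecutive k-mers.

    For ``kmerize("CAGCU", 2)`` the tokens are CA, AG, GC, CU.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(sequence):
        raise ValueError(f"k={k} exceeds sequence length {len(sequence)}")
    kmers = [sequence[i:i + k] for i in range(len(sequence) - k + 1)]
    ids = np.array([_kmer_id(m) for m in kmers], dtype=np.int64)
    return KmerView(scale=k, kmers=kmers, token_ids=ids)


def _kmer_id(kmer: str) -> int:
    """Lexicographic integer id over the A<C<G<U ordering."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def tokenize_ids(sequence: str, k: int) -> np.ndarray:
    return kmerize(sequence, k).token_ids


def vocabulary(k: int) -> list[str]:
    """All 4**k k-mers in stable lexicographic (A<C<G<U) order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def export_vocabulary_tsv(config: TokenizerConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("scale\ttoken\tid\n")
        for k in config.scales:
            for token in vocabulary(k):
                fh.write(f"{k}\t{token}\t{_kmer_id(token)}\n")
            fh.write(f"{k}\t{config.pad_symbol}\t{config.pad_id(k)}\n")


class CoverageMap:
    """For every base position, the (scale, token-slot) pairs covering it.

    ``slots[k]`` is an (L, k) integer array: row p lists the k token start
    positions whose k-mer contains base p, with -1 marking slots that fall
    outside the sequence (completed by the scale's pad token).  Coverage is
    a function of the window length and scales only, never of base content.
    """

    PAD = -1

    def __init__(self, length: int, config: TokenizerConfig):
        self.length = length
        self.config = config
        self.slots: dict[int, np.ndarray] = {}
        for k in config.scales:
            slot = np.empty((length, k), dtype=np.int64)
            n_tokens = length - k + 1
            for p in range(length):
                starts = np.arange(p - k + 1, p + 1)
                starts[(starts < 0) | (starts >= n_tokens)] = self.PAD
                slot[p] = starts
            self.slots[k] = slot

    def entries(self, p: int) -> list[tuple[int, int]]:
        """All (scale, slot) pairs covering base p; slot -1 means pad."""
        return [(k, int(s)) for k in self.config.scales for s in self.slots[k][p]]

    @property
    def candidates_per_base(self) -> int:
        return self.config.candidates_per_base


def build_coverage(sequence_or_length, config: TokenizerConfig | None = None
                   ) -> CoverageMap:
    """Coverage map for a sequence (or directly for its length)."""
    if config is None:
        config = TokenizerConfig()
    length = (sequence_or_length if isinstance(sequence_or_length, int)
              else len(sequence_or_length))
    return CoverageMap(length, config)


@dataclass
class SoftAttentionStage:
    """Additive soft-attention parameters: projection W, bias b, scorer v."""

    W: Tensor
    b: Tensor
    v: Tensor


def soft_attention_fuse(candidates, stage: SoftAttentionStage
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fuse candidate vectors into one convex combination.

    Returns (fused vector, attention weights); weights are nonnegative and
    sum to one.  ``candidates`` is an (m, d) array or a list of d-vectors.
    """
    E = np.asarray([np.asarray(c, dtype=np.float64) for c in candidates])
    if E.ndim != 2 or E.shape[0] == 0:
        raise ValueError("need at least one candidate vector")
    scores = np.tanh(E @ stage.W.data.T + stage.b.data) @ stage.v.data
    scores = scores - scores.max()
    w = np.exp(scores)
    w = w / w.sum()
    return w @ E, w


def _fuse_tensor(E: Tensor, stage: SoftAttentionStage) -> Tensor:
    """Tensor-path soft attention over axis -2 of E (..., m, d) -> (..., d)."""
    d = E.shape[-1]
    h = ad.tanh(ad.matmul(E, ad.swapaxes(stage.W, 0, 1)) + stage.b)
    scores = ad.matmul(h, ad.reshape(stage.v, (d, 1)))      # (..., m, 1)
    w = ad.softmax(scores, axis=-2)
    return ad.tsum(w * E, axis=-2)


def _score_table(table: Tensor, stage: SoftAttentionStage) -> Tensor:
    """Soft-attention score of every vocabulary row: (V, 1).

    The additive score v . tanh(W e + b) depends only on the candidate
    vector e, so it is computed once per vocabulary entry and gathered,
    rather than per occurrence; the result is identical.
    """
    d = table.shape[-1]
    h = ad.tanh(ad.matmul(table, ad.swapaxes(stage.W, 0, 1)) + stage.b)
    return ad.matmul(h, ad.reshape(stage.v, (d, 1)))


@dataclass
class PositionEncodingConfig:
    """Fixed sinusoidal encoding constants: base b, model width, token length."""

    b: float = 1000.0
    d_model: int = 64
    length: int = WINDOW_LENGTH + 2

    def __post_init__(self):
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even")
        if self.b <= 0:
            raise ValueError("b must be positive")


def position_encoding(config: PositionEncodingConfig | None = None) -> np.ndarray:
    """PE(pos, 2i) = sin(pos / b^(2i/d)); PE(pos, 2i+1) = cos(pos / b^(2i/d))."""
    if config is None:
        config = PositionEncodingConfig()
    pos = np.arange(config.length, dtype=np.float64)[:, None]
    i = np.arange(config.d_model // 2, dtype=np.float64)[None, :]
    angle = pos / (config.b ** (2.0 * i / config.d_model))
    pe = np.empty((config.length, config.d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class EmbeddingParams:
    """Learnable parameters of the multi-sense-scaled embedding.

    One table per (scale, sense) pair, each with a trailing pad row; one
    soft-attention stage for scale fusion (shared by all senses) and one for
    sense fusion; learned start/end boundary vectors.
    """

    def __init__(self, config: TokenizerConfig, n_senses: int, d_model: int,
                 rng: np.random.Generator):
        if n_senses < 1:
            raise ValueError("need at least one sense")
        self.config = config
        self.n_senses = n_senses
        self.d_model = d_model
        # Token tables and boundary vectors start at unit scale so sequence
        # content is commensurate with the O(1) sinusoidal position encoding;
        # a 1/sqrt(d_model) table scale buries content 8x below the PE and
        # the normalised encoder stack then barely varies between inputs.
        self.tables: dict[tuple[int, int], Tensor] = {}
        for k in config.scales:
            for m in range(n_senses):
                self.tables[(k, m)] = Tensor(
                    rng.normal(0.0, 1.0, size=(config.vocab_size(k), d_model)),
                    requires_grad=True)
        stage_scale = 1.0 / np.sqrt(d_model)
        self.scale_stage = self._init_stage(rng, d_model, stage_scale)
        self.sense_stage = self._init_stage(rng, d_model, stage_scale)
        self.start = Tensor(rng.normal(0.0, 1.0, size=d_model),
                            requires_grad=True)
        self.end = Tensor(rng.normal(0.0, 1.0, size=d_model),
                          requires_grad=True)

    @staticmethod
    def _init_stage(rng, d_model, scale) -> SoftAttentionStage:
        return SoftAttentionStage(
            W=Tensor(rng.normal(0.0, scale, size=(d_model, d_model)),
                     requires_grad=True),
            b=Tensor(np.zeros(d_model), requires_grad=True),
            v=Tensor(rng.normal(0.0, scale, size=d_model), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        params = [self.tables[key] for key in sorted(self.tables)]
        for stage in (self.scale_stage, self.sense_stage):
            params.extend([stage.W, stage.b, stage.v])
        params.extend([self.start, self.end])
        return params


def init_embedding_params(config: TokenizerConfig | None = None,
                          n_senses: int = 3, d_model: int = 64,
                          rng: np.random.Generator | None = None
                          ) -> EmbeddingParams:
    if config is None:
        config = TokenizerConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    return EmbeddingParams(config, n_senses, d_model, rng)


def candidate_ids(sequences_ids: dict[int, np.ndarray],
                  coverage: CoverageMap) -> dict[int, np.ndarray]:
    """Per scale: (B, L, k) candidate token ids (pad slots -> pad id)."""
    out = {}
    for k, slot in coverage.slots.items():
        ids = sequences_ids[k]                        # (B, L-k+1)
        pad_col = np.full((ids.shape[0], 1), coverage.config.pad_id(k),
                          dtype=np.int64)
        ids_ext = np.concatenate([ids, pad_col], axis=1)
        out[k] = ids_ext[:, slot]                     # slot -1 -> last column
    return out


def embed_tokens_batch(cand: dict[int, np.ndarray],
                       params: EmbeddingParams) -> Tensor:
    """Differentiable token embedding of a batch: (B, L+2, d_model)."""
    B = next(iter(cand.values())).shape[0]
    L = next(iter(cand.values())).shape[1]
    sense_rows = []
    for m in range(params.n_senses):
        parts = [ad.take(params.tables[(k, m)], cand[k])
                 for k in params.config.scales]       # each (B, L, k, d)
        E = parts[0] if len(parts) == 1 else ad.concat(parts, axis=2)
        score_parts = [ad.take(_score_table(params.tables[(k, m)],
                                            params.scale_stage), cand[k])
                       for k in params.config.scales]  # each (B, L, k, 1)
        scores = (score_parts[0] if len(score_parts) == 1
                  else ad.concat(score_parts, axis=2))
        w = ad.softmax(scores, axis=-2)               # over the candidates
        fused = ad.tsum(w * E, axis=-2)               # (B, L, d)
        sense_rows.append(ad.reshape(fused, (B, L, 1, params.d_model)))
    if params.n_senses == 1:
        base = ad.reshape(sense_rows[0], (B, L, params.d_model))
    else:
        S = ad.concat(sense_rows, axis=2)             # (B, L, senses, d)
        base = _fuse_tensor(S, params.sense_stage)
    zeros = Tensor(np.zeros((B, 1, params.d_model),
                            dtype=params.start.data.dtype))
    start = zeros + ad.reshape(params.start, (1, 1, params.d_model))
    end = zeros + ad.reshape(params.end, (1, 1, params.d_model))
    return ad.concat([start, base, end], axis=1)      # (B, L+2, d)


def embed_tokens(window: RnaWindow, params: EmbeddingParams,
                 coverage: CoverageMap | None = None) -> np.ndarray:
    """Token-embedding matrix of one window: (43, 64), boundaries included."""
    if coverage is None:
        coverage = build_coverage(window.sequence, params.config)
    seq_ids = {k: tokenize_ids(window.sequence, k)[None, :]
               for k in params.config.scales}
    cand = candidate_ids(seq_ids, coverage)
    with ad.no_grad():
        out = embed_tokens_batch(cand, params)
    return out.data[0]


def embed_sequence(window: RnaWindow, params: EmbeddingParams,
                   pe: np.ndarray | None = None) -> np.ndarray:
    """Token embedding plus fixed position encoding (no scaling factor)."""
    tokens = embed_tokens(window, params)
    if pe is None:
        pe = position_encoding(PositionEncodingConfig(
            d_model=params.d_model, length=tokens.shape[0]))
    if pe.shape != tokens.shape:
        raise ValueError(f"position-encoding shape {pe.shape} does not match "
                         f"token matrix {tokens.shape}")
    return tokens + pe
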