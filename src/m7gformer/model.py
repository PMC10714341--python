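"""The full classifier: embedding -> encoder stack -> pooled softmax head.

``ModelConfig`` mirrors the reference setting (64-dim embedding over k-mer
scales 1-3 with 3 senses, 3 encode blocks of 8 heads with d_k = 32, size-1
convolutional sublayer, FFN hidden 64, head hidden 16, dropout 0.5) and
carries the ablation switches.  ``variant_config`` maps the named ablation
variants onto those switches:

* ``TE+Encoder``      - plain 1-mer single-sense embedding, no position
                        encoding, no convolutional sublayer
* ``TE+PE+Encoder``   - adds the sinusoidal position encoding
* ``MSSE+PE+Encoder`` - adds the multi-sense-scaled embedding
* ``full``            - adds the convolutional sublayer
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import autodiff as ad
from . import embedding as emb
from . import encoder as enc
from . import head as hd
from .autodiff import Tensor
from .sequence_io import LabeledDataset, WINDOW_LENGTH

__all__ = ["ModelConfig", "M7GModel", "variant_config", "ABLATION_VARIANTS",
           "save_checkpoint", "load_checkpoint"]

ABLATION_VARIANTS = ("TE+Encoder", "TE+PE+Encoder", "MSSE+PE+Encoder", "full")

CHECKPOINT_FORMAT = "m7gformer-checkpoint-v1"


@dataclass
class ModelConfig:
    d_model: int = 64
    scales: tuple[int, ...] = (1, 2, 3)
    n_senses: int = 3
    n_blocks: int = 3
    n_heads: int = 8
    d_k: int = 32
    ffn_hidden: int = 64
    head_hidden: int = 16
    dropout: float = 0.5
    pe_base: float = 1000.0
    use_position_encoding: bool = True
    use_conv: bool = True
    pooling: str = "mean"
    window_length: int = WINDOW_LENGTH
    learned_position_embedding: bool = False  # config stub; rejected below

    def __post_init__(self):
        if self.learned_position_embedding:
            raise NotImplementedError(
                "adaptive (learned) position embeddings are not supported; "
                "the fixed sinusoidal encoding is the implemented choice")
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even (sinusoidal encoding)")

    @property
    def token_length(self) -> int:
        return self.window_length + 2

    def encoder_config(self) -> enc.EncoderConfig:
        return enc.EncoderConfig(n_blocks=self.n_blocks, dropout=self.dropout,
                                 use_conv=self.use_conv,
                                 use_position_encoding=self.use_position_encoding)


def variant_config(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Config for a named ablation variant, derived from ``base``."""
    base = base or ModelConfig()
    if name == "TE+Encoder":
        return replace(base, scales=(1,), n_senses=1,
                       use_position_encoding=False, use_conv=False)
    if name == "TE+PE+Encoder":
        return replace(base, scales=(1,), n_senses=1,
                       use_position_encoding=True, use_conv=False)
    if name == "MSSE+PE+Encoder":
        return replace(base, use_position_encoding=True, use_conv=False)
    if name == "full":
        return replace(base, use_position_encoding=True, use_conv=True)
    raise ValueError(f"unknown ablation variant {name!r}; "
                     f"choose from {ABLATION_VARIANTS}")


class M7GModel:
    """Parameter container plus the differentiable forward pass."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.tokenizer = emb.TokenizerConfig(scales=tuple(self.config.scales))
        self.embedding = emb.EmbeddingParams(self.tokenizer,
                                             self.config.n_senses,
                                             self.config.d_model, rng)
        self.blocks = [
            enc.init_block_params(rng, self.config.d_model,
                                  self.config.n_heads, self.config.d_k,
                                  self.config.ffn_hidden)
            for _ in range(self.config.n_blocks)
        ]
        self.head = hd.init_head_params(rng, self.config.d_model,
                                        self.config.head_hidden,
                                        self.config.pooling,
                                        self.config.dropout)
        self.coverage = emb.build_coverage(self.config.window_length,
                                           self.tokenizer)
        self.pe = emb.position_encoding(emb.PositionEncodingConfig(
            b=self.config.pe_base, d_model=self.config.d_model,
            length=self.config.token_length))

    def cast(self, dtype) -> "M7GModel":
        """Cast all parameters (and the cached position encoding) in place.

        float32 roughly halves training time at this model size; float64 is
        the default so structural checks hold at tight tolerances.
        """
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        self.pe = self.pe.astype(dtype)
        return self

    # -- parameters ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = list(self.embedding.parameters())
        for block in self.blocks:
            params.extend(enc.block_parameters(block))
        params.extend(hd.head_parameters(self.head))
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- data preparation ----------------------------------------------
    def encode_sequences(self, sequences: list[str]) -> dict[int, np.ndarray]:
        """Per-scale token-id arrays for a list of equal-length windows."""
        ids = {}
        for k in self.tokenizer.scales:
            ids[k] = np.stack([emb.tokenize_ids(s, k) for s in sequences])
        return emb.candidate_ids(ids, self.coverage)

    # -- forward -------------------------------------------------------
    def forward(self, cand: dict[int, np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (logits (B,2), pooled (B,d), encoded (B,43,d))."""
        x = emb.embed_tokens_batch(cand, self.embedding)
        if self.config.use_position_encoding:
            x = x + Tensor(self.pe)
        encoded = enc.encode(x, self.blocks, self.config.encoder_config(),
                             training, rng)
        pooled = hd.pool(encoded, self.config.pooling)
        logits = hd.head_logits(pooled, self.head, training, rng)
        return logits, pooled, encoded

    def loss(self, cand: dict[int, np.ndarray], labels: np.ndarray,
             training: bool = True, rng: np.random.Generator | None = None
             ) -> tuple[Tensor, np.ndarray]:
        """Mean cross-entropy over the batch; also returns p_pos per sample."""
        logits, _, _ = self.forward(cand, training, rng)
        logp = ad.log_softmax(logits, axis=-1)
        onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
        onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
        nll = -ad.tsum(logp * Tensor(onehot)) / len(labels)
        with ad.no_grad():
            p_pos = np.exp(logp.data[:, 1] - np.logaddexp(logp.data[:, 0],
                                                          logp.data[:, 1]))
        return nll, p_pos

    # -- inference -----------------------------------------------------
    def predict_proba(self, dataset_or_sequences, batch_size: int = 256
                      ) -> np.ndarray:
        """Eval-mode p_pos for every window, in input order."""
        if isinstance(dataset_or_sequences, LabeledDataset):
            sequences = dataset_or_sequences.sequences()
        else:
            sequences = list(dataset_or_sequences)
        out = np.empty(len(sequences))
        with ad.no_grad():
            for lo in range(0, len(sequences), batch_size):
                chunk = sequences[lo:lo + batch_size]
                cand = self.encode_sequences(chunk)
                logits, _, _ = self.forward(cand, training=False)
                z = logits.data
                out[lo:lo + len(chunk)] = np.exp(
                    z[:, 1] - np.logaddexp(z[:, 0], z[:, 1]))
        return out

    def pooled_features(self, dataset_or_sequences, batch_size: int = 256
                        ) -> np.ndarray:
        """Eval-mode pooled 64-vectors (the learned features) per window."""
        if isinstance(dataset_or_sequences, LabeledDataset):
            sequences = dataset_or_sequences.sequences()
        else:
            sequences = list(dataset_or_sequences)
        rows = []
        with ad.no_grad():
            for lo in range(0, len(sequences), batch_size):
                cand = self.encode_sequences(sequences[lo:lo + batch_size])
                _, pooled, _ = self.forward(cand, training=False)
                rows.append(pooled.data)
        return np.concatenate(rows, axis=0)


# -- checkpointing -----------------------------------------------------

def save_checkpoint(model: M7GModel, path, seed: int | None = None) -> None:
    """Bundle config, every parameter array and the seed into one .npz file."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    cfg = asdict(model.config)
    cfg["scales"] = list(cfg["scales"])
    meta = {"format": CHECKPOINT_FORMAT, "config": cfg, "seed": seed}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> M7GModel:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
    if meta.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"unrecognised checkpoint format: {meta.get('format')}")
    cfg_dict = meta["config"]
    cfg_dict["scales"] = tuple(cfg_dict["scales"])
    model = M7GModel(ModelConfig(**cfg_dict), seed=meta.get("seed") or 0)
    for i, p in enumerate(model.parameters()):
        arr = data[f"param_{i}"]
        if arr.shape != p.data.shape:
            raise ValueError("checkpoint parameter shape mismatch")
        p.data = arr.astype(np.float64)
    return model
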