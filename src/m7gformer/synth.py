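"""Synthetic 41-nt G-centered windows with a planted positional motif.

Negatives are iid uniform over {A,C,G,U} apart from the obligatory center G.
Positives share that background but, across a fixed motif window, sample
bases from motif probability columns mixed with the uniform background by a
``strength`` in [0, 1] (0 = pure background, 1 = pure motif).  The planted
motif is therefore the only structure separating the classes, which is what
makes these datasets suitable for learning-sanity and ablation checks.

The default motif spans offsets 14-19 (immediately upstream of the center)
with one-hot columns at strength 0.9, an effective information content of
about 9 bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import (ALPHABET, CENTER_INDEX, LabeledDataset, RnaWindow,
                          WINDOW_LENGTH, write_fasta)

__all__ = ["MotifSpec", "SynthConfig", "default_motif", "generate_dataset",
           "motif_information_content", "write_synthetic_fasta"]


@dataclass
class MotifSpec:
    """Positional probability columns (A,C,G,U order) planted in positives."""

    offset: int
    columns: np.ndarray  # (width, 4), each row a probability vector

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("columns must be (width, 4)")
        if np.any(self.columns < 0):
            raise ValueError("column probabilities must be nonnegative")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each motif column must sum to 1")
        if self.offset < 0 or self.offset + self.width > WINDOW_LENGTH:
            raise ValueError("motif must fit inside the window")
        center_col = CENTER_INDEX - self.offset
        if 0 <= center_col < self.width:
            if self.columns[center_col, ALPHABET.index("G")] != 1.0:
                raise ValueError("a motif overlapping the center must fix G "
                                 "there")

    @property
    def width(self) -> int:
        return self.columns.shape[0]


def default_motif() -> MotifSpec:
    """One-hot columns spelling AAUGGA at offsets 14-19."""
    bases = "AAUGGA"
    cols = np.zeros((len(bases), 4))
    for i, b in enumerate(bases):
        cols[i, ALPHABET.index(b)] = 1.0
    return MotifSpec(offset=14, columns=cols)


@dataclass
class SynthConfig:
    n_pos: int = 400
    n_neg: int = 400
    length: int = WINDOW_LENGTH
    seed: int = 0
    motif: MotifSpec = field(default_factory=default_motif)
    strength: float = 0.9

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.length != WINDOW_LENGTH:
            raise ValueError(f"windows are fixed at {WINDOW_LENGTH} nt")


def _sample_windows(rng: np.random.Generator, n: int,
                    column_probs: np.ndarray) -> np.ndarray:
    """Sample n windows; column_probs is (length, 4) per-position probabilities."""
    u = rng.random((n, column_probs.shape[0]))
    cum = np.cumsum(column_probs, axis=1)
    return (u[:, :, None] < cum[None, :, :]).argmax(axis=2)


def generate_dataset(cfg: SynthConfig | None = None) -> LabeledDataset:
    """Seeded dataset of n_pos motif-bearing and n_neg background windows."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    uniform = np.full((cfg.length, 4), 0.25)
    uniform[CENTER_INDEX] = 0.0
    uniform[CENTER_INDEX, ALPHABET.index("G")] = 1.0

    pos_probs = uniform.copy()
    sl = slice(cfg.motif.offset, cfg.motif.offset + cfg.motif.width)
    pos_probs[sl] = (cfg.strength * cfg.motif.columns
                     + (1.0 - cfg.strength) * 0.25)
    pos_probs[CENTER_INDEX] = uniform[CENTER_INDEX]

    windows = []
    base_arr = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    for label, n, probs, tag in ((1, cfg.n_pos, pos_probs, "pos"),
                                 (0, cfg.n_neg, uniform, "neg")):
        idx = _sample_windows(rng, n, probs)
        chars = base_arr[idx]
        for i in range(n):
            windows.append(RnaWindow(id=f"synth_{tag}_{i}",
                                     sequence=chars[i].tobytes().decode(),
                                     label=label))
    return LabeledDataset(windows)


def motif_information_content(motif: MotifSpec) -> float:
    """Total information content in bits: sum over columns of 2 + sum p log2 p."""
    cols = motif.columns
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(cols > 0, cols * np.log2(cols), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))


def write_synthetic_fasta(cfg: SynthConfig, pos_path, neg_path,
                          provenance_path=None) -> LabeledDataset:
    """Emit paired positive/negative FASTA plus a provenance JSON."""
    dataset = generate_dataset(cfg)
    write_fasta(dataset, pos_path, neg_path)
    if provenance_path is not None:
        prov = {
            "n_pos": cfg.n_pos, "n_neg": cfg.n_neg, "length": cfg.length,
            "seed": cfg.seed, "strength": cfg.strength,
            "motif_offset": cfg.motif.offset,
            "motif_columns": cfg.motif.columns.tolist(),
            "motif_bits": motif_information_content(cfg.motif),
        }
        with open(provenance_path, "w") as fh:
            json.dump(prov, fh, indent=2)
    return dataset
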