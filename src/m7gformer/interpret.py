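"""Interpretability outputs: feature export, occlusion importance, base frequencies.

* ``export_features`` writes the pooled 64-dim representation of every
  window (the input expected by external 2-D projection tools such as UMAP).
* ``positional_importance`` scores each of the 41 positions by occlusion:
  the drop in predicted positive probability when the base at that position
  is replaced, averaged over the three alternative bases.  Positive values
  mark positions the model relies on for a positive call.
* ``position_frequency_table`` tabulates per-position base frequencies,
  suitable as input to sequence-logo tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import M7GModel
from .sequence_io import ALPHABET, LabeledDataset, WINDOW_LENGTH

__all__ = [
    "FeatureMatrix",
    "ImportanceMatrix",
    "export_features",
    "positional_importance",
    "position_frequency_table",
    "write_features_tsv",
    "write_importance_tsv",
    "write_frequency_tsv",
]


@dataclass
class FeatureMatrix:
    features: np.ndarray  # (n, 64)
    ids: list[str]
    labels: np.ndarray
    epoch: int | None = None


@dataclass
class ImportanceMatrix:
    values: np.ndarray  # (n, 41)
    ids: list[str]

    def per_position_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


def export_features(model: M7GModel, dataset: LabeledDataset,
                    epoch: int | None = None) -> FeatureMatrix:
    """Pooled eval-mode representations for downstream 2-D projection."""
    feats = model.pooled_features(dataset)
    return FeatureMatrix(features=feats, ids=dataset.ids(),
                         labels=dataset.labels(), epoch=epoch)


def positional_importance(model: M7GModel, dataset: LabeledDataset,
                          batch_size: int = 512) -> ImportanceMatrix:
    """Occlusion importance: p_pos(original) minus the mean p_pos over the
    three single-base substitutions at each position (center included)."""
    sequences = dataset.sequences()
    n = len(sequences)
    original = model.predict_proba(sequences)

    variants: list[str] = []
    for seq in sequences:
        for p in range(WINDOW_LENGTH):
            for b in ALPHABET:
                if b != seq[p]:
                    variants.append(seq[:p] + b + seq[p + 1:])
    scores = model.predict_proba(variants, batch_size=batch_size)
    scores = scores.reshape(n, WINDOW_LENGTH, 3)
    values = original[:, None] - scores.mean(axis=2)
    return ImportanceMatrix(values=values, ids=dataset.ids())


def position_frequency_table(dataset: LabeledDataset,
                             label_filter: int | None = None) -> np.ndarray:
    """(41, 4) per-position base frequencies (A,C,G,U order); rows sum to 1."""
    windows = [w for w in dataset
               if label_filter is None or w.label == label_filter]
    if not windows:
        raise ValueError("no windows left after label filtering")
    counts = np.zeros((WINDOW_LENGTH, 4))
    for w in windows:
        for p, ch in enumerate(w.sequence):
            counts[p, ALPHABET.index(ch)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


# -- TSV writers -------------------------------------------------------

def write_features_tsv(fm: FeatureMatrix, path) -> None:
    d = fm.features.shape[1]
    with open(path, "w") as fh:
        fh.write("id\tlabel\t" + "\t".join(f"f{i+1}" for i in range(d)) + "\n")
        for i, (wid, lab) in enumerate(zip(fm.ids, fm.labels)):
            row = "\t".join(f"{v:.6g}" for v in fm.features[i])
            fh.write(f"{wid}\t{lab}\t{row}\n")


def write_importance_tsv(im: ImportanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"p{i+1}" for i in range(WINDOW_LENGTH))
                 + "\n")
        for wid, row in zip(im.ids, im.values):
            fh.write(wid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_frequency_tsv(freqs: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tA\tC\tG\tU\n")
        for p, row in enumerate(freqs):
            fh.write(f"{p}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
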