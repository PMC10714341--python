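"""Reading, validating, labelling and splitting 41-nt RNA windows.

The positive class is a 41-nt window centered on an m7G-modified guanosine
(20 nt of flank on each side); inputs arrive as plain FASTA, one file per
class.  DNA-alphabet files (T instead of U) are accepted and converted by
default.  Splitting and k-fold assignment are stratified and seeded so that
every protocol run is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

WINDOW_LENGTH = 41
CENTER_INDEX = 20
ALPHABET = "ACGU"

__all__ = [
    "WINDOW_LENGTH",
    "CENTER_INDEX",
    "ALPHABET",
    "RnaWindow",
    "LabeledDataset",
    "SplitSpec",
    "read_fasta",
    "read_labeled_fasta",
    "write_fasta",
    "validate_window",
    "split_train_test",
    "make_cv_folds",
    "export_assignment_tsv",
]


@dataclass
class RnaWindow:
    """One candidate window: id, 41-nt RNA sequence, binary label (1 = m7G)."""

    id: str
    sequence: str
    label: int


class LabeledDataset:
    """Ordered collection of :class:`RnaWindow` with per-class counts."""

    def __init__(self, windows: list[RnaWindow]):
        self.windows = list(windows)

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]

    @property
    def n_pos(self) -> int:
        return sum(1 for w in self.windows if w.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for w in self.windows if w.label == 0)

    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.windows[i] for i in indices])

    def __add__(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self.windows + other.windows)


@dataclass
class SplitSpec:
    """Train/test split: fraction of each class kept for training."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def validate_window(window: RnaWindow, require_center_g: bool = True) -> list[str]:
    """Return a list of invariant violations (empty when the window is valid).

    Violations are data, not exceptions: callers decide whether to raise.
    """
    violations = []
    seq = window.sequence
    if len(seq) != WINDOW_LENGTH:
        violations.append(
            f"length is {len(seq)}, expected {WINDOW_LENGTH}")
    for pos, ch in enumerate(seq):
        if ch not in ALPHABET:
            violations.append(
                f"invalid character {ch!r} at position {pos} "
                f"(alphabet {{A,C,G,U}})")
    if require_center_g and len(seq) == WINDOW_LENGTH and seq[CENTER_INDEX] != "G":
        violations.append(
            f"center position {CENTER_INDEX} is {seq[CENTER_INDEX]!r}, "
            f"expected 'G'")
    return violations


def read_fasta(path, label: int, convert_t: bool = True,
               require_center_g: bool = True) -> LabeledDataset:
    """Read one FASTA file into a dataset, every record given ``label``.

    ``convert_t`` replaces T with U (DNA-alphabet input) before validation.
    A record violating the window invariants raises ValueError naming the
    record and the violation.  Duplicate ids are allowed but warned about.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    windows = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if convert_t:
            seq = seq.replace("T", "U")
        window = RnaWindow(id=record.id, sequence=seq, label=int(label))
        violations = validate_window(window, require_center_g=require_center_g)
        if violations:
            raise ValueError(
                f"record {record.id!r} in {path}: " + "; ".join(violations))
        if record.id in seen:
            warnings.warn(f"duplicate record id {record.id!r} in {path}")
        seen.add(record.id)
        windows.append(window)
    return LabeledDataset(windows)


def read_labeled_fasta(pos_path, neg_path, convert_t: bool = True,
                       require_center_g: bool = True) -> LabeledDataset:
    """Read a positive and a negative FASTA file into one dataset."""
    pos = read_fasta(pos_path, 1, convert_t=convert_t,
                     require_center_g=require_center_g)
    neg = read_fasta(neg_path, 0, convert_t=convert_t,
                     require_center_g=require_center_g)
    return pos + neg


def write_fasta(dataset: LabeledDataset, pos_path, neg_path) -> None:
    """Write the dataset back to per-class FASTA files (round-trip safe)."""
    for label, path in ((1, pos_path), (0, neg_path)):
        records = [SeqRecord(Seq(w.sequence), id=w.id, description="")
                   for w in dataset if w.label == label]
        SeqIO.write(records, str(path), "fasta")


def _round_count(fraction: float, n: int) -> int:
    return int(np.floor(fraction * n + 0.5))


def split_train_test(dataset: LabeledDataset,
                     spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive, seeded train/test partition.

    When stratified, each class is split at ``train_fraction`` separately so
    per-class proportions are within one sample of the target.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    labels = dataset.labels()
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        for cls in (1, 0):
            cls_idx = np.flatnonzero(labels == cls)
            if cls_idx.size == 0:
                raise ValueError(
                    f"stratified split requires both classes; class {cls} empty")
            perm = rng.permutation(cls_idx)
            n_train = _round_count(spec.train_fraction, perm.size)
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
    else:
        perm = rng.permutation(len(dataset))
        n_train = _round_count(spec.train_fraction, perm.size)
        train_idx = list(perm[:n_train])
        test_idx = list(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return dataset.subset(train_idx), dataset.subset(test_idx)


def make_cv_folds(dataset: LabeledDataset, k: int, seed: int = 0,
                  stratified: bool = True) -> np.ndarray:
    """Assign every window to one of ``k`` folds; returns fold index per window.

    Stratified assignment gives every fold floor(n_class/k) members of each
    class and places each class's remainder on the folds with the smallest
    running totals, so per-class counts and overall fold sizes both differ
    by at most one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = dataset.labels()
    rng = np.random.default_rng(seed)
    folds = np.empty(len(dataset), dtype=int)
    if stratified:
        totals = np.zeros(k, dtype=int)
        for cls in (1, 0):
            cls_idx = np.flatnonzero(labels == cls)
            if cls_idx.size < k:
                raise ValueError(
                    f"class {cls} has {cls_idx.size} members, fewer than k={k}")
            perm = rng.permutation(cls_idx)
            base, rem = divmod(perm.size, k)
            counts = np.full(k, base)
            counts[np.argsort(totals, kind="stable")[:rem]] += 1
            folds[perm] = np.repeat(np.arange(k), counts)
            totals += counts
    else:
        if len(dataset) < k:
            raise ValueError(f"dataset smaller than k={k}")
        perm = rng.permutation(len(dataset))
        folds[perm] = np.arange(len(dataset)) % k
    return folds


def export_assignment_tsv(dataset: LabeledDataset, assignment, path) -> None:
    """Write a two-column TSV of (id, fold-or-partition) pairs."""
    with open(path, "w") as fh:
        fh.write("id\tassignment\n")
        for w, a in zip(dataset, assignment):
            fh.write(f"{w.id}\t{a}\n")
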