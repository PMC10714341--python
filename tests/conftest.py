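"""Shared fixtures.

The trained-model fixtures are session-scoped because training, even on the
small synthetic task, dominates suite runtime; the learning-sanity,
ablation-direction and motif-recovery tests all share the same three seeded
full-model runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import m7gformer as mg
from m7gformer.sequence_io import SplitSpec, split_train_test
from m7gformer.train import TrainConfig, train

TRAIN_SEEDS = (1, 2, 3)
TRAIN_EPOCHS = 20  # within the short-training protocol used for sanity runs


def synthetic_task(seed: int):
    """The reference synthetic task: 400+400 windows, strength-0.9 motif."""
    ds = mg.generate_dataset(mg.SynthConfig(n_pos=400, n_neg=400, seed=seed))
    return split_train_test(ds, SplitSpec(seed=seed))


def _train_variant(variant: str, seed: int, shuffle_labels: bool = False):
    train_set, test_set = synthetic_task(seed)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1000)
        labels = rng.permutation(train_set.labels())
        shuffled = mg.LabeledDataset([
            mg.RnaWindow(w.id, w.sequence, int(l))
            for w, l in zip(train_set, labels)])
        train_set = shuffled
    cfg = TrainConfig(epochs=TRAIN_EPOCHS, seed=seed, variant=variant)
    model, losses = train(None, train_set, cfg)
    return model, losses, train_set, test_set


@pytest.fixture(scope="session")
def trained_full_models():
    """Full model trained on the synthetic task for each seed."""
    return {seed: _train_variant("full", seed) for seed in TRAIN_SEEDS}


@pytest.fixture(scope="session")
def trained_te_models():
    """TE+Encoder ablation variant trained identically."""
    return {seed: _train_variant("TE+Encoder", seed) for seed in TRAIN_SEEDS}


@pytest.fixture(scope="session")
def shuffled_label_models():
    """Full model trained on label-shuffled data (no learnable signal)."""
    return {seed: _train_variant("full", seed, shuffle_labels=True)
            for seed in TRAIN_SEEDS}
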