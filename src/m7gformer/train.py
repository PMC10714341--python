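"""Training protocol, metric suite, cross-validation and ablation runs.

Training follows the reference setting: Adam (lr 1e-4, default moments),
batch size 32, cross-entropy loss, a fixed number of epochs with no early
stopping, minibatches reshuffled every epoch under a seed.  Evaluation
reports ACC / Pr / Sn / Sp (percent), F1, AUC, MCC and the mean per-sample
cross-entropy.  Ratios with a zero denominator are reported as 0 and
flagged rather than raised, so degenerate folds stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (precision_recall_curve, roc_auc_score,
                             roc_curve)

from .model import ABLATION_VARIANTS, M7GModel, ModelConfig, variant_config
from .sequence_io import LabeledDataset, make_cv_folds

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "MetricsReport",
    "CvSummary",
    "Adam",
    "train",
    "predict_scores",
    "confusion",
    "compute_metrics",
    "auc",
    "evaluate",
    "cross_validate",
    "run_ablation",
    "roc_points",
    "pr_points",
    "write_curve_tsv",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    deterministic: bool = True
    variant: str = "full"
    precision: str = "float32"  # training dtype; "float64" for exactness

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be "
                             "positive")
        if self.variant not in ABLATION_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """ACC/Pr/Sn/Sp in percent; F1, AUC, MCC unitless; Loss mean cross-entropy."""

    ACC: float
    Pr: float
    Sn: float
    Sp: float
    F1: float
    AUC: float
    MCC: float
    Loss: float
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("ACC", "Pr", "Sn", "Sp", "F1", "AUC", "MCC", "Loss")}


@dataclass
class CvSummary:
    folds: list[MetricsReport]

    def mean(self) -> dict:
        return {k: float(np.mean([f.as_dict()[k] for f in self.folds]))
                for k in self.folds[0].as_dict()}

    def std(self) -> dict:
        return {k: float(np.std([f.as_dict()[k] for f in self.folds]))
                for k in self.folds[0].as_dict()}


class Adam:
    """Adam with default moment parameters (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1c
            vhat = self.v[i] / b2c
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train(model_config: ModelConfig | None, train_set: LabeledDataset,
          cfg: TrainConfig) -> tuple[M7GModel, list[float]]:
    """Train for exactly ``cfg.epochs`` epochs; returns model and loss curve.

    The model is initialised from ``cfg.seed``; minibatch order and dropout
    masks are seeded too, so identical configs reproduce identical runs.
    A single-class training set warns but proceeds.
    """
    import warnings

    if len(train_set) == 0:
        raise ValueError("training set is empty")
    labels = train_set.labels()
    if len(np.unique(labels)) < 2:
        warnings.warn("training set contains a single class")

    base = model_config or ModelConfig()
    config = variant_config(cfg.variant, base)
    model = M7GModel(config, seed=cfg.seed).cast(np.dtype(cfg.precision))

    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, dropout_rng = [np.random.default_rng(c)
                                for c in ss.spawn(2)]

    cand_all = model.encode_sequences(train_set.sequences())
    n = len(train_set)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    losses: list[float] = []
    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            cand = {k: v[idx] for k, v in cand_all.items()}
            opt.zero_grad()
            loss, _ = model.loss(cand, labels[idx], training=True,
                                 rng=dropout_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}: {loss.data!r}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return model, losses


def predict_scores(model: M7GModel, dataset: LabeledDataset) -> np.ndarray:
    """Eval-mode p_pos per window, in dataset order."""
    return model.predict_proba(dataset)


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & pred)),
        TN=int(np.sum((labels == 0) & ~pred)),
        FP=int(np.sum((labels == 0) & pred)),
        FN=int(np.sum((labels == 1) & ~pred)),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def auc(scores, labels) -> float:
    """ROC area = Mann-Whitney probability (ties counted 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cross_entropy(labels, scores, eps: float = 1e-12) -> float:
    """Mean per-sample cross-entropy of p_pos against binary labels."""
    labels = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(scores, dtype=float), eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def compute_metrics(counts: ConfusionCounts, labels=None,
                    scores=None) -> MetricsReport:
    """Full metric suite from confusion counts (AUC/Loss need scores)."""
    if counts.n == 0:
        raise ValueError("cannot compute metrics on zero samples")
    deg: list[str] = []
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    acc = 100.0 * (tp + tn) / counts.n
    pr = 100.0 * _ratio(tp, tp + fp, "Pr", deg)
    sn = 100.0 * _ratio(tp, tp + fn, "Sn", deg)
    sp = 100.0 * _ratio(tn, tn + fp, "Sp", deg)
    f1 = _ratio(2 * (pr / 100) * (sn / 100), pr / 100 + sn / 100, "F1", deg)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "MCC", deg)
    auc_val = np.nan
    loss_val = np.nan
    if labels is not None and scores is not None:
        if len(np.unique(np.asarray(labels, dtype=int))) >= 2:
            auc_val = auc(scores, labels)
        else:
            deg.append("AUC")
            auc_val = 0.0
        loss_val = cross_entropy(labels, scores)
    return MetricsReport(ACC=acc, Pr=pr, Sn=sn, Sp=sp, F1=f1,
                         AUC=auc_val, MCC=mcc, Loss=loss_val, degenerate=deg)


def evaluate(model: M7GModel, dataset: LabeledDataset,
             threshold: float = 0.5) -> MetricsReport:
    scores = predict_scores(model, dataset)
    labels = dataset.labels()
    return compute_metrics(confusion(labels, scores, threshold),
                           labels, scores)


def roc_points(labels, scores) -> np.ndarray:
    """(threshold, FPR, TPR) rows of the ROC curve."""
    fpr, tpr, thr = roc_curve(np.asarray(labels, int),
                              np.asarray(scores, float))
    return np.column_stack([thr, fpr, tpr])


def pr_points(labels, scores) -> np.ndarray:
    """(threshold, recall, precision) rows of the precision-recall curve."""
    pr, rc, thr = precision_recall_curve(np.asarray(labels, int),
                                         np.asarray(scores, float))
    thr = np.r_[thr, np.inf]  # final (recall 0) point has no threshold
    return np.column_stack([thr, rc, pr])


def write_curve_tsv(points: np.ndarray, header: tuple[str, str, str],
                    path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in points:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def cross_validate(dataset: LabeledDataset, model_config: ModelConfig | None,
                   cfg: TrainConfig, k: int = 10) -> CvSummary:
    """k-fold CV: fresh seeded initialisation (seed + fold) per fold."""
    folds = make_cv_folds(dataset, k, seed=cfg.seed)
    reports = []
    for fold in range(k):
        train_set = dataset.subset(np.flatnonzero(folds != fold))
        test_set = dataset.subset(np.flatnonzero(folds == fold))
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        model, _ = train(model_config, train_set, fold_cfg)
        reports.append(evaluate(model, test_set))
    return CvSummary(folds=reports)


def run_ablation(train_set: LabeledDataset, test_set: LabeledDataset,
                 variants=ABLATION_VARIANTS, cfg: TrainConfig | None = None,
                 model_config: ModelConfig | None = None
                 ) -> dict[str, MetricsReport]:
    """Train/evaluate each variant on identical splits and seeds."""
    cfg = cfg or TrainConfig()
    results: dict[str, MetricsReport] = {}
    for name in variants:
        model, _ = train(model_config, train_set, replace(cfg, variant=name))
        results[name] = evaluate(model, test_set)
    return results
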