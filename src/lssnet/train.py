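"""Training loop, stratified splitting, evaluation metrics, and the ablation
harness.

Metrics follow the standard confusion-matrix definitions:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with zero-denominator ratios reported as 0 and flagged. ROC points come from
a sweep over the unique predicted severe-class probabilities (equal scores
collapse to one threshold); AUC is the trapezoidal area, which equals the
rank-sum (Mann-Whitney) statistic up to tie handling.

Training uses Adam (lr 0.001, betas 0.9/0.999, eps 1e-8), 2-class
cross-entropy, on-the-fly augmentation of the training pass, and early
stopping on a monitored validation quantity (default: validation loss,
patience 10). The 80:20 stratified split doubles as the early-stopping
validation set, reproducing the published protocol; an optional
``val_fraction`` carves a separate validation set out of the training side.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment
from .autograd import Tensor, cross_entropy, no_grad, softmax
from .network import (
    BRANCHES,
    NetworkConfig,
    StenosisNet,
    build_ablation_variant,
)
from .phantom import LabeledImage
from .preprocess import (
    PreprocessConfig,
    apply_demean,
    channel_means,
    normalize_intensity,
    resize_bilinear,
)

__all__ = [
    "TrainConfig", "ConfusionCounts", "MetricsReport",
    "stratified_split_indices", "stratified_split",
    "confusion_from_predictions", "compute_metrics", "roc_auc",
    "EarlyStopper", "prepare_arrays", "train", "evaluate_model",
    "run_ablation", "TrainingDiverged",
]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    split_ratio: float = 0.8
    monitor: str = "val_loss"  # or "val_accuracy"
    val_fraction: float = 0.0  # >0 carves a separate validation split
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("val_loss", "val_accuracy"):
            raise ValueError("monitor must be val_loss or val_accuracy")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def stratified_split_indices(labels: Sequence[int], ratio: float,
                             seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class `ratio` : 1-ratio partition; disjoint and exhaustive."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        rng.shuffle(idx)
        cut = int(round(ratio * idx.size))
        cut = min(max(cut, 1), idx.size - 1)  # both sides nonempty per class
        train_idx.append(idx[:cut])
        test_idx.append(idx[cut:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def stratified_split(dataset: Sequence[LabeledImage], cfg: TrainConfig):
    tr, te = stratified_split_indices([d.label for d in dataset],
                                      cfg.split_ratio, cfg.seed)
    return [dataset[i] for i in tr], [dataset[i] for i in te]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: ConfusionCounts
    degenerate: dict = field(default_factory=dict)
    roc_points: np.ndarray | None = None
    auc: float | None = None


def confusion_from_predictions(y_true: Sequence[int],
                               y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("label/prediction length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Scalar metrics from confusion counts; 0/0 ratios -> 0 with a flag."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    degenerate = {}
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        precision, degenerate["precision"] = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate["recall"] = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1, degenerate["f1"] = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, confusion=counts, degenerate=degenerate)


def roc_auc(scores: Sequence[float],
            labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a unique-score threshold sweep; trapezoidal
    AUC. Equal scores are treated as a single threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------


class EarlyStopper:
    """Stop when the monitored value fails to improve for `patience` epochs.

    ``mode='min'`` for losses, ``'max'`` for accuracies. ``update`` returns
    True when training should stop; ``best_epoch`` is 1-based.
    """

    def __init__(self, patience: int, mode: str = "min"):
        if mode not in ("min", "max"):
            raise ValueError("mode must be min or max")
        self.patience = patience
        self.mode = mode
        self.best: float | None = None
        self.best_epoch = 0
        self._bad = 0

    def update(self, value: float, epoch: int) -> bool:
        improved = (self.best is None
                    or (self.mode == "min" and value < self.best)
                    or (self.mode == "max" and value > self.best))
        if improved:
            self.best = value
            self.best_epoch = epoch
            self._bad = 0
        else:
            self._bad += 1
        return self._bad >= self.patience


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def prepare_arrays(train_set: Sequence[LabeledImage],
                   test_set: Sequence[LabeledImage],
                   pre_cfg: PreprocessConfig = PreprocessConfig()):
    """Run the deterministic pipeline and return model-ready arrays.

    Normalize -> resize -> demean, with the demeaning statistic computed on
    the training split only. Returns (X_train, y_train, X_test, y_test) with
    X of shape (N, 1, H, W) float32.
    """

    def _norm_resize(items):
        return [resize_bilinear(normalize_intensity(d.image.astype(np.float64),
                                                    pre_cfg), pre_cfg)
                for d in items]

    tr = _norm_resize(train_set)
    te = _norm_resize(test_set)
    means = channel_means(tr) if pre_cfg.demean else np.zeros(1)
    tr = apply_demean(tr, means)
    te = apply_demean(te, means)
    xtr = np.stack(tr)[:, None].astype(np.float32)
    xte = np.stack(te)[:, None].astype(np.float32)
    ytr = np.array([d.label for d in train_set])
    yte = np.array([d.label for d in test_set])
    return xtr, ytr, xte, yte, means


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _epoch_eval(model: StenosisNet, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float, np.ndarray]:
    """Mean loss, accuracy, and severe-class scores in eval mode."""
    model.eval()
    losses, scores = [], []
    with no_grad():
        for i in range(0, len(x), batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            logits = model(Tensor(xb))
            losses.append(float(cross_entropy(logits, yb).data) * len(yb))
            scores.append(softmax(logits, axis=1).data[:, 1])
    scores = np.concatenate(scores)
    preds = (scores >= 0.5).astype(int)
    return float(np.sum(losses) / len(x)), float(np.mean(preds == y)), scores


def train(model_cfg: NetworkConfig, train_cfg: TrainConfig,
          dataset: Sequence[LabeledImage],
          aug_cfg: AugmentConfig | None = None,
          pre_cfg: PreprocessConfig = PreprocessConfig(),
          ) -> tuple[StenosisNet, pd.DataFrame, MetricsReport]:
    """Train the classifier on a labelled dataset; fully seeded.

    Returns the best-epoch model, the per-epoch log, and the metrics of the
    best model on the held-out split.
    """
    from .nn import Adam  # local import to keep module load light

    if aug_cfg is None:
        aug_cfg = AugmentConfig(seed=train_cfg.seed)
    train_set, test_set = stratified_split(dataset, train_cfg)
    if train_cfg.val_fraction > 0.0:
        inner = TrainConfig(seed=train_cfg.seed + 1,
                            split_ratio=1.0 - train_cfg.val_fraction)
        train_set, val_set = stratified_split(train_set, inner)
    else:
        val_set = test_set
    xtr, ytr, xva, yva, _ = prepare_arrays(train_set, val_set, pre_cfg)

    model = StenosisNet(model_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    stopper = EarlyStopper(train_cfg.patience,
                           "min" if train_cfg.monitor == "val_loss" else "max")
    log_rows = []
    best_state = None
    for epoch in range(1, train_cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(xtr))
        epoch_loss = 0.0
        for i in range(0, len(order), train_cfg.batch_size):
            sel = order[i:i + train_cfg.batch_size]
            xb = np.stack([
                augment(xtr[j, 0], aug_cfg, rng).astype(np.float32)
                for j in sel])[:, None]
            yb = ytr[sel]
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
        epoch_loss /= len(xtr)
        val_loss, val_acc, _ = _epoch_eval(model, xva, yva,
                                           train_cfg.batch_size)
        log_rows.append({"epoch": epoch, "train_loss": epoch_loss,
                         "val_loss": val_loss, "val_accuracy": val_acc})
        monitored = val_loss if train_cfg.monitor == "val_loss" else val_acc
        stop = stopper.update(monitored, epoch)
        if stopper.best_epoch == epoch or best_state is None:
            best_state = copy.deepcopy(model.state_dict())
        if stop:
            break
    model.load_state_dict(best_state)
    xtr2, ytr2, xte, yte, _ = prepare_arrays(train_set, test_set, pre_cfg)
    report = evaluate_model(model, xte, yte, train_cfg.batch_size)
    log = pd.DataFrame(log_rows)
    log.attrs["best_epoch"] = stopper.best_epoch
    return model, log, report


def evaluate_model(model: StenosisNet, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 32) -> MetricsReport:
    """Confusion-matrix metrics plus ROC/AUC on preprocessed arrays."""
    _, _, scores = _epoch_eval(model, x, y, batch_size)
    counts = confusion_from_predictions(y, (scores >= 0.5).astype(int))
    report = compute_metrics(counts)
    if len(np.unique(y)) == 2:
        report.roc_points, report.auc = roc_auc(scores, y)
    return report


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------


def run_ablation(base_cfg: NetworkConfig, train_cfg: TrainConfig,
                 dataset: Sequence[LabeledImage],
                 aug_cfg: AugmentConfig | None = None,
                 pre_cfg: PreprocessConfig = PreprocessConfig(),
                 ) -> pd.DataFrame:
    """Train the full model plus three minus-one and three only-one variants
    under identical seed, split, and schedule; one row of metrics each."""
    variants = [("full", base_cfg)]
    variants += [(f"without_{b}", build_ablation_variant(base_cfg, drop=b))
                 for b in BRANCHES]
    variants += [(f"only_{b}", build_ablation_variant(base_cfg, keep_only=b))
                 for b in BRANCHES]
    rows = []
    for name, cfg in variants:
        _, log, report = train(cfg, train_cfg, dataset, aug_cfg, pre_cfg)
        rows.append({
            "variant": name,
            "branches": "+".join(cfg.enabled_branches),
            "accuracy": report.accuracy,
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
            "auc": report.auc,
            "epochs_run": len(log),
        })
    return pd.DataFrame(rows)
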