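"""Dataset splitting, imbalance-aware sampling, and Adam training.

Class imbalance is handled by weighted sampling with replacement: each
record's weight is the inverse of its class frequency, so every class is
drawn with expected probability 1/K.  The loss is the batch-mean
cross-entropy; model selection keeps the weights with the best validation
loss, with early stopping on a configurable patience.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _nn
from .exceptions import (
    ContractViolationError,
    InvalidParameterError,
    TrainingDivergedError,
)
from .gpg_core import build_gpg
from .graph_model import (
    AblationModel,
    GPGCNModel,
    ModelConfig,
    graphs_to_arrays,
)

SPLITS = ("train", "val", "test")


@dataclass
class LabeledDataset:
    """Sequence records with integer labels, optional aux features, splits."""

    ids: list[str]
    sequences: list[str]
    labels: np.ndarray  # int, in [0, K)
    split: np.ndarray  # str, one of SPLITS
    aux: np.ndarray | None = None  # (N, a) or None

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.sequences) == n == len(self.labels) == len(self.split)):
            raise ContractViolationError("record arrays have inconsistent lengths")
        if self.aux is not None and len(self.aux) != n:
            raise ContractViolationError("aux feature table length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            split=self.split[idx],
            aux=self.aux[idx] if self.aux is not None else None,
        )


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise InvalidParameterError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be > 0")


def _allocate(n: int, ratios) -> list[int]:
    """Largest-remainder rounding of n into len(ratios) parts."""
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # most-short first
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(
    ids,
    sequences,
    labels,
    ratios=(0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = True,
    aux=None,
) -> LabeledDataset:
    """Assign every record to exactly one of train/val/test.

    Stratified mode shuffles and allocates within each class so that class
    proportions are preserved per split up to rounding.  Deterministic for a
    given seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidParameterError(f"ratios {ratios} must sum to 1")
    labels = np.asarray(labels, dtype=np.int64)
    n = len(ids)
    rng = np.random.default_rng(seed)
    split = np.empty(n, dtype=object)
    if stratified:
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            sizes = _allocate(len(idx), ratios)
            pos = 0
            for name, size in zip(SPLITS, sizes):
                split[idx[pos : pos + size]] = name
                pos += size
    else:
        idx = rng.permutation(n)
        sizes = _allocate(n, ratios)
        pos = 0
        for name, size in zip(SPLITS, sizes):
            split[idx[pos : pos + size]] = name
            pos += size
    return LabeledDataset(
        ids=list(ids),
        sequences=list(sequences),
        labels=labels,
        split=split.astype(str),
        aux=np.asarray(aux, dtype=np.float64) if aux is not None else None,
    )


def sample_weights(labels) -> np.ndarray:
    """Inverse-class-frequency weight per record."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise InvalidParameterError("empty label list")
    counts = np.bincount(labels)
    if (counts[np.unique(labels)] == 0).any():
        raise InvalidParameterError("every class must have at least one record")
    return 1.0 / counts[labels]


def cross_entropy(probs, labels, n_classes: int, eps: float = 1e-12) -> float:
    """Batch-mean negative log-probability of the true class."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.shape[1] != n_classes:
        raise ContractViolationError("probability width does not match n_classes")
    if (labels < 0).any() or (labels >= n_classes).any():
        raise InvalidParameterError("labels out of range")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p_true, eps))))


# ---------------------------------------------------------------------------
# encoding


def window_sequences(ids, sequences, labels, aux, window: int):
    """Cut sequences into non-overlapping windows of fixed length.

    Each full window becomes its own record carrying its parent's label and
    aux features; sequences shorter than the window are kept whole.
    """
    w_ids, w_seqs, w_labels, w_aux, parent = [], [], [], [], []
    for i, (sid, seq) in enumerate(zip(ids, sequences)):
        chunks = [seq[j : j + window] for j in range(0, len(seq) - window + 1, window)]
        if not chunks:
            chunks = [seq]
        for j, chunk in enumerate(chunks):
            w_ids.append(f"{sid}|w{j}")
            w_seqs.append(chunk)
            w_labels.append(labels[i])
            parent.append(i)
            if aux is not None:
                w_aux.append(aux[i])
    return (
        w_ids,
        w_seqs,
        np.asarray(w_labels, dtype=np.int64),
        np.asarray(w_aux) if aux is not None else None,
        np.asarray(parent),
    )


def encode_split(dataset: LabeledDataset, config: ModelConfig, split: str):
    """Graph-encode one split into stacked feature arrays.

    Returns ``(H_u, H_v, aux, labels)``; applies windowing when
    ``config.window > 0``.
    """
    idx = dataset.indices(split)
    ids = [dataset.ids[i] for i in idx]
    seqs = [dataset.sequences[i] for i in idx]
    labels = dataset.labels[idx]
    aux = dataset.aux[idx] if dataset.aux is not None else None
    if config.window > 0:
        ids, seqs, labels, aux, _ = window_sequences(ids, seqs, labels, aux, config.window)
    graphs = [
        build_gpg(s, k=config.k, d=config.d, binning=config.binning) for s in seqs
    ]
    H_u, H_v = graphs_to_arrays(graphs, config)
    return H_u, H_v, aux, labels


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainResult:
    params: dict
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _eval(model, H_u, H_v, aux, labels, batch_size=64):
    losses, correct = [], 0
    for i in range(0, len(labels), batch_size):
        a = aux[i : i + batch_size] if aux is not None else None
        logits, _ = model.forward(H_u[i : i + batch_size], H_v[i : i + batch_size], a)
        loss, _ = _nn.softmax_cross_entropy(logits, labels[i : i + batch_size])
        losses.append(loss * (min(i + batch_size, len(labels)) - i))
        correct += int((logits.argmax(axis=1) == labels[i : i + batch_size]).sum())
    return sum(losses) / len(labels), correct / len(labels)


def train(model, dataset: LabeledDataset, config: TrainConfig) -> TrainResult:
    """Train with Adam on weighted-sampled mini-batches.

    Minimizes the batch-mean cross-entropy; keeps the weights with the best
    validation loss; stops early after ``patience`` epochs without
    improvement.  Deterministic for a given seed.
    """
    for split in ("train", "val"):
        if len(dataset.indices(split)) == 0:
            raise InvalidParameterError(f"dataset has an empty {split} split")
    mcfg = model.config
    Xu_tr, Xv_tr, aux_tr, y_tr = encode_split(dataset, mcfg, "train")
    Xu_va, Xv_va, aux_va, y_va = encode_split(dataset, mcfg, "val")

    weights = sample_weights(y_tr)
    probs = weights / weights.sum()
    rng = np.random.default_rng(config.seed)
    optimizer = _nn.Adam(model.params, lr=config.learning_rate)
    n_train = len(y_tr)
    batches_per_epoch = int(np.ceil(n_train / config.batch_size))

    best = model.copy_params()
    best_loss, best_epoch, stale = np.inf, -1, 0
    rows = []
    for epoch in range(config.max_epochs):
        draw = rng.choice(n_train, size=batches_per_epoch * config.batch_size, p=probs)
        epoch_loss = 0.0
        for b in range(batches_per_epoch):
            idx = draw[b * config.batch_size : (b + 1) * config.batch_size]
            a = aux_tr[idx] if aux_tr is not None else None
            logits, cache = model.forward(Xu_tr[idx], Xv_tr[idx], a)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            grads = model.backward(dlogits, cache)
            optimizer.step(grads)
            epoch_loss += loss
        val_loss, val_acc = _eval(model, Xu_va, Xv_va, aux_va, y_va)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / batches_per_epoch,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best_loss:
            best_loss, best_epoch, stale = val_loss, epoch, 0
            best = model.copy_params()
        else:
            stale += 1
            if stale > config.patience:
                break
    model.set_params(best)
    return TrainResult(
        params=best,
        history=pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss", "val_accuracy"]),
        best_epoch=best_epoch,
        best_val_loss=float(best_loss),
    )


def evaluate(model, dataset: LabeledDataset, split: str = "test"):
    """Accuracy and macro-F1 of a trained model on one split."""
    Xu, Xv, aux, y = encode_split(dataset, model.config, split)
    _, acc = _eval(model, Xu, Xv, aux, y)
    logits_pred = []
    for i in range(0, len(y), 64):
        a = aux[i : i + 64] if aux is not None else None
        logits, _ = model.forward(Xu[i : i + 64], Xv[i : i + 64], a)
        logits_pred.append(logits.argmax(axis=1))
    pred = np.concatenate(logits_pred)
    return acc, macro_f1(y, pred, model.config.n_classes)


def macro_f1(y_true, y_pred, n_classes: int) -> float:
    """Unweighted mean of per-class F1 scores."""
    f1s = []
    for c in range(n_classes):
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = int(((y_pred != c) & (y_true == c)).sum())
        f1s.append(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s))


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    grid: dict,
    dataset: LabeledDataset,
    train_config: TrainConfig,
    base_config: ModelConfig,
    metric: str = "accuracy",
):
    """Train one model per grid cell; select the best validation score.

    ``grid`` maps ModelConfig field names (e.g. ``d``, ``n_layers``,
    ``window``) to candidate lists.  Ties are broken by grid order (first
    cell wins).  Returns ``(best_config, scores)`` where scores is a
    DataFrame with one row per cell.
    """
    if not grid:
        raise InvalidParameterError("empty grid")
    if metric not in ("accuracy", "macro_f1"):
        raise InvalidParameterError(f"unknown metric {metric!r}")
    keys = list(grid.keys())
    rows = []
    best_cfg, best_score = None, -np.inf
    for values in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base_config, **dict(zip(keys, values)))
        model = GPGCNModel(cfg)
        train(model, dataset, train_config)
        Xu, Xv, aux, y = encode_split(dataset, cfg, "val")
        _, acc = _eval(model, Xu, Xv, aux, y)
        if metric == "accuracy":
            score = acc
        else:
            pred = []
            for i in range(0, len(y), 64):
                a = aux[i : i + 64] if aux is not None else None
                logits, _ = model.forward(Xu[i : i + 64], Xv[i : i + 64], a)
                pred.append(logits.argmax(axis=1))
            score = macro_f1(y, np.concatenate(pred), cfg.n_classes)
        rows.append({**dict(zip(keys, values)), "val_score": score})
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, pd.DataFrame(rows)
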