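"""Training protocol: file-level stratified hold-out, instance-level
stratified k-fold cross-validation, class-weighted loss, Adam with a
plateau learning-rate schedule, early stopping and best-weight restore.

All randomness (splits, folds, initialisation, batching, dropout) derives
from a single integer seed, so two runs with the same configuration are
reproducible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Adam, ReduceLROnPlateau, Tensor, cross_entropy

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SplitPlan", "stratified_file_split", "stratified_kfold",
           "class_weights", "train_model", "predict", "evaluate_loss"]


@dataclass
class TrainConfig:
    test_frac: float = 0.10
    k: int = 6
    lr: float = 1e-3
    weight_decay: float = 1e-5
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 64
    batch_size: int = 64
    seed: int = 0
    use_class_weights: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_frac < 1.0:
            raise ValueError(f"test_frac must be in (0, 1), got {self.test_frac}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        for name in ("plateau_patience", "early_stop_patience", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SplitPlan:
    train_files: list[str]
    test_files: list[str]
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def stratified_file_split(files: list[tuple[str, str]], test_frac: float = 0.10,
                          seed: int = 0) -> tuple[list[str], list[str]]:
    """Per class, allocate ``round(test_frac * n_c)`` files (at least one) to
    the hold-out set by seeded shuffle.  Requires >= 2 files per class."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for file_id, label in files:
        by_class.setdefault(label, []).append(file_id)
    train, test = [], []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if len(ids) < 2:
            raise ValueError(
                f"class {label!r} has {len(ids)} file(s); cannot stratify a hold-out split")
        n_test = max(1, round(test_frac * len(ids)))
        rng.shuffle(ids)
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return sorted(train), sorted(test)


def stratified_kfold(labels: list | np.ndarray, k: int = 6,
                     seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold over instances; every instance lands in
    exactly one validation fold and class proportions are preserved to within
    one instance."""
    labels = np.asarray(labels)
    counts = Counter(labels.tolist())
    for label, n in counts.items():
        if n < k:
            raise ValueError(f"class {label!r} has {n} instances < k={k}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for label in sorted(counts, key=str):
        idx = np.flatnonzero(labels == label)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    folds = []
    for f in range(k):
        val = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        folds.append((train, val))
    return folds


def class_weights(labels: list | np.ndarray) -> np.ndarray:
    """Inverse-frequency weights w_c = N / (K * n_c) over integer-coded labels.

    The sample-weighted mean of the weights is exactly 1.
    """
    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels)
    if np.any(counts == 0):
        raise ValueError("every class in [0, K) must be present")
    return labels.size / (counts.size * counts.astype(np.float64))


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def predict(model: nn.Module, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode argmax predictions."""
    model.eval()
    preds = []
    with nn.no_grad():
        for start in range(0, len(X), batch_size):
            logits = model(Tensor(X[start:start + batch_size]))
            preds.append(np.argmax(logits.data, axis=1))
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)


def evaluate_loss(model: nn.Module, X: np.ndarray, y: np.ndarray,
                  weights: np.ndarray | None, batch_size: int = 256) -> float:
    model.eval()
    total, wsum = 0.0, 0.0
    with nn.no_grad():
        for start in range(0, len(X), batch_size):
            xb, yb = X[start:start + batch_size], y[start:start + batch_size]
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb, weights)
            w = len(yb) if weights is None else weights[yb].sum()
            total += loss.data.item() * w
            wsum += w
    return total / wsum


def train_model(model: nn.Module, train_data: tuple[np.ndarray, np.ndarray],
                val_data: tuple[np.ndarray, np.ndarray], cfg: TrainConfig,
                weights: np.ndarray | None = None) -> tuple[nn.Module, dict]:
    """Fit with Adam on class-weighted cross-entropy.

    Validation loss drives the plateau scheduler and early stopping; the
    returned model carries the weights of the best validation epoch.  The
    history dict records per-epoch train/val loss, val accuracy and lr.
    """
    X_tr, y_tr = train_data
    X_val, y_val = val_data
    if len(X_tr) == 0 or len(X_val) == 0:
        raise ValueError("train and validation folds must be nonempty")
    if weights is None and cfg.use_class_weights:
        weights = class_weights(y_tr)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                              patience=cfg.plateau_patience)
    history = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        model.train()
        epoch_loss, n_seen = 0.0, 0
        for batch in _iter_batches(len(X_tr), cfg.batch_size, rng):
            if len(batch) < 2:
                continue  # batch-norm needs batch statistics
            xb, yb = X_tr[batch], y_tr[batch]
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb, weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.data.item() * len(batch)
            n_seen += len(batch)
        val_loss = evaluate_loss(model, X_val, y_val, weights)
        val_acc = float(np.mean(predict(model, X_val) == y_val))
        history["train_loss"].append(epoch_loss / max(n_seen, 1))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        sched.step(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best val loss %.6f)",
                            epoch, best_val)
                break
    model.load_state_dict(best_state)
    history["best_val_loss"] = best_val
    return model, history
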