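"""Training loop and frame-level evaluation for the detector.

The loss is a class-weighted binary cross entropy over the ten frame
decisions of each window: positive-frame errors are up-weighted by a factor
``beta`` (default 2) to counter the imbalance between fQRS-containing and
empty frames.  Optimization is Adam (lr 1e-3, beta1 0.9, beta2 0.999,
eps 1e-8), Xavier/Glorot initialization, dropout 0.4, and the checkpoint
with the best validation F1 is kept.

Evaluation is frame-level: each 100 ms frame is one classification unit,
predicted positive when the positive-class probability wins the argmax.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np

from .data_windows import SignalWindow, standardize_windows, windows_to_arrays
from .network import OctResNet, softmax_last
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TrainResult",
    "weighted_bce_loss",
    "loss_from_logits",
    "train",
    "evaluate",
    "metrics_from_counts",
]

PROB_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 100
    batch_size: int = 64
    loss_beta: float = 2.0
    seed: int = 0
    normalize: bool = True  # per-window per-channel standardization

    def __post_init__(self) -> None:
        if self.loss_beta <= 0:
            raise ValueError("loss_beta must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class MetricsReport:
    """Frame-level detection counts and derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    degenerate: bool = False  # a zero denominator was hit

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "degenerate": self.degenerate,
        }


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int = 0) -> MetricsReport:
    """Precision/recall/F1 with the zero-denominator convention metric = 0."""
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return MetricsReport(tp, fp, fn, tn, precision, recall, f1, degenerate)


def weighted_bce_loss(predictions: np.ndarray, labels: np.ndarray, beta: float = 2.0) -> float:
    """Class-weighted binary cross entropy (functional form).

    ``predictions`` holds positive-class probabilities, shape (M, T) (or a
    (M, T, 2) probability-pair array, in which case column 1 is used).
    Returns ``(1/M) sum_i sum_j -[beta y log p + (1 - y) log(1 - p)]``.
    """
    p = np.asarray(predictions, dtype=float)
    if p.ndim >= 2 and p.shape[-1] == 2 and np.asarray(labels).shape != p.shape:
        p = p[..., 1]
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"predictions {p.shape} and labels {y.shape} mismatch")
    if p.ndim == 1:
        p, y = p[None], y[None]
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    per_frame = -(beta * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(per_frame.sum(axis=tuple(range(1, p.ndim))).mean())


def loss_from_logits(logits: Tensor, labels: np.ndarray, beta: float) -> Tensor:
    """Differentiable weighted BCE on the two-class logits (B, T, 2).

    The positive-class probability of a two-way softmax equals
    sigmoid(z1 - z0), so the loss is computed on the logit difference for
    numerical stability.
    """
    b, t, _ = logits.data.shape
    z0 = logits.slice_last(0, 1).reshape(b, t)
    z1 = logits.slice_last(1, 2).reshape(b, t)
    p = (z1 - z0).sigmoid().clip(PROB_EPS, 1.0 - PROB_EPS)
    y = Tensor(np.asarray(labels, dtype=logits.data.dtype))
    one = Tensor(np.ones((), dtype=logits.data.dtype))
    terms = y * p.log() * float(beta) + (one - y) * (one - p).log()
    return terms.mean() * (-float(t))


@dataclass
class TrainResult:
    """Training history plus the selected model state."""

    history: list[dict]
    best_epoch: int
    best_val_f1: float
    best_state: list[np.ndarray] = field(repr=False, default_factory=list)

    def as_dict(self) -> dict:
        return {
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_val_f1": self.best_val_f1,
        }


def _prepare(data, normalize: bool) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        x, y = data
    else:
        x, y = windows_to_arrays(list(data))
    x = np.asarray(x, dtype=np.float32)
    if normalize:
        x = standardize_windows(x).astype(np.float32)
    return x, np.asarray(y)


def train(
    model: OctResNet,
    train_data,
    val_data,
    config: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> TrainResult:
    """Run the optimization recipe and keep the best-validation-F1 weights.

    ``train_data``/``val_data`` are lists of :class:`SignalWindow` or
    ``(x, y)`` array pairs.  Fully seeded: initialization is the model's,
    data order and dropout masks derive from ``config.seed``.  The selected
    state is restored into ``model`` before returning.
    """
    x_train, y_train = _prepare(train_data, config.normalize)
    x_val, y_val = _prepare(val_data, config.normalize)
    if not len(x_train) or not len(x_val):
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng((config.seed, 3))
    model.seed_dropout(config.seed)
    opt = Adam(
        model.parameters(),
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        epsilon=config.epsilon,
    )
    history: list[dict] = []
    best_f1, best_epoch, best_state = -1.0, -1, None
    n = len(x_train)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        t0 = time.time()
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            logits = model.forward_logits(Tensor(x_train[idx]))
            loss = loss_from_logits(logits, y_train[idx], config.loss_beta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {s // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_metrics = evaluate(model, (x_val, y_val), normalize=False)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_f1": val_metrics.f1,
                "val_precision": val_metrics.precision,
                "val_recall": val_metrics.recall,
                "seconds": time.time() - t0,
            }
        )
        if verbose:
            h = history[-1]
            print(
                f"epoch {epoch:3d}  loss {h['train_loss']:.4f}  "
                f"val F1 {h['val_f1']:.4f}  ({h['seconds']:.1f}s)",
                flush=True,
            )
        if val_metrics.f1 > best_f1:
            best_f1, best_epoch = val_metrics.f1, epoch
            best_state = [a.copy() for a in model.state_arrays()]
    model.load_state_arrays(best_state)
    return TrainResult(history, best_epoch, best_f1, best_state)


def evaluate(
    model: OctResNet,
    data,
    batch_size: int = 64,
    normalize: bool = True,
) -> MetricsReport:
    """Frame-level precision/recall/F1 of the model on labeled windows."""
    x, y = _prepare(data, normalize)
    preds = np.empty_like(y)
    for s in range(0, len(x), batch_size):
        probs = model.predict_proba(x[s : s + batch_size])
        preds[s : s + batch_size] = np.argmax(probs, axis=-1)
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    return metrics_from_counts(tp, fp, fn, tn)
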