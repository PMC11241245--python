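"""Training loop: cross-entropy, SGD, plateau LR reduction, early stopping.

The loss is the mean multi-class cross-entropy
``-sum_c y_{o,c} log p_{o,c}`` over observations o, and the optimizer is
plain stochastic gradient descent ``w <- w - gamma * grad`` with optional
momentum and decoupled weight decay (the decay term is added to the update,
not to the loss).  The learning rate is reduced by a factor of 0.1 when the
validation loss plateaus, and training halts early when it has not
improved for ``early_stop_patience`` epochs.  Reference hyperparameters:
learning rate 0.001, weight decay 0.01, batch size 16, at most 50 epochs,
early-stopping patience 25.
"""

from __future__ import annotations

import csv
import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-12
IMPROVEMENT_TOL = 1e-8  # "improvement" = strictly lower val loss by at least this


def cross_entropy(probabilities: np.ndarray, one_hot: np.ndarray) -> float:
    """Mean cross-entropy of a row-stochastic probability batch.

    ``probabilities``: N x M rows summing to 1; ``one_hot``: N x M with a
    single 1 per row.  Probabilities are clipped away from zero at 1e-12.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(one_hot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if not (np.all((y == 0) | (y == 1)) and np.all(y.sum(axis=1) == 1)):
        raise ValueError("targets must be one-hot")
    return float(-(y * np.log(np.clip(p, EPS, None))).sum(axis=1).mean())


@dataclass
class OptimizerState:
    """Functional single-parameter SGD state (the update-rule surface)."""

    weights: np.ndarray
    learning_rate: float
    weight_decay: float = 0.0
    epoch: int = 0
    best_val_loss: float = math.inf
    epochs_since_improvement: int = 0


def sgd_step(state: OptimizerState, gradient: np.ndarray) -> OptimizerState:
    """One SGD update ``w <- w - gamma * (g + weight_decay * w)``.

    With weight_decay 0 this is the plain descent rule.  A non-finite
    gradient raises and leaves the state unchanged.
    """
    g = np.asarray(gradient, dtype=np.float64)
    if g.shape != np.shape(state.weights):
        raise ValueError("gradient shape does not match weights")
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite gradient")
    w = np.asarray(state.weights, dtype=np.float64)
    new_w = w - state.learning_rate * (g + state.weight_decay * w)
    return OptimizerState(
        weights=new_w,
        learning_rate=state.learning_rate,
        weight_decay=state.weight_decay,
        epoch=state.epoch,
        best_val_loss=state.best_val_loss,
        epochs_since_improvement=state.epochs_since_improvement,
    )


@dataclass
class TrainingConfig:
    lr: float = 0.001
    weight_decay: float = 0.01
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_patience: int = 25
    lr_factor: float = 0.1
    scheduler_patience: int = 5
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lr", "weight_decay", "batch_size", "max_epochs",
                     "early_stop_patience", "lr_factor", "scheduler_patience"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.early_stop_patience < 1 or self.scheduler_patience < 1:
            raise ValueError("patience values must be >= 1")


class SGD:
    """Mini-batch SGD over a parameter list, with momentum and decoupled decay."""

    def __init__(self, parameters, lr: float, weight_decay: float = 0.0,
                 momentum: float = 0.0):
        self.parameters = list(parameters)
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.parameters, self._velocity):
            if p.grad is None:
                continue
            update = p.grad + self.weight_decay * p.data
            if self.momentum > 0.0:
                v *= self.momentum
                v += update
                update = v
            p.data = p.data - self.lr * update


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without validation-loss improvement."""

    def __init__(self, optimizer: SGD, factor: float = 0.1, patience: int = 5):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = math.inf
        self.stale = 0

    def step(self, val_loss: float) -> bool:
        """Register an epoch's validation loss; returns True if LR dropped."""
        if not math.isfinite(val_loss):
            raise ValueError("validation loss must be finite")
        if val_loss < self.best - IMPROVEMENT_TOL:
            self.best = val_loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            return True
        return False


class EarlyStopping:
    """Halt when validation loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int = 25):
        self.patience = patience
        self.best = math.inf
        self.stale = 0

    def step(self, val_loss: float) -> bool:
        if val_loss < self.best - IMPROVEMENT_TOL:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float
    lr: float


@dataclass
class History:
    records: list = field(default_factory=list)

    def append(self, rec: EpochRecord) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc", "lr"])
            for r in self.records:
                w.writerow([r.epoch, r.train_loss, r.train_acc, r.val_loss, r.val_acc, r.lr])

    def final(self) -> EpochRecord:
        return self.records[-1]


def evaluate_loss(model, batches) -> tuple:
    """Mean loss and accuracy of a model over an iterable of (x, y) batches."""
    total, correct, loss_sum = 0, 0, 0.0
    model.eval()
    with ad.no_grad():
        for x, y in batches:
            logits = model(Tensor(x)).data
            p = ad.softmax(logits)
            idx = np.arange(len(y))
            loss_sum += float(-np.log(np.clip(p[idx, y], EPS, None)).sum())
            correct += int((p.argmax(axis=1) == y).sum())
            total += len(y)
    if total == 0:
        raise ValueError("empty evaluation stream")
    return loss_sum / total, correct / total


def train(model, train_stream, val_stream, config: TrainingConfig,
          out_dir=None, verbose: bool = False):
    """Run the training loop; returns (model, History).

    ``train_stream`` must expose ``batches(batch_size, epoch_index)``
    yielding standardized (N, 3, side, side) float batches with integer
    labels; ``val_stream`` must expose ``batches(batch_size)``.  The
    best-validation-loss weights are restored at the end (and written to
    ``out_dir`` when given, along with the per-epoch CSV history and a run
    manifest).
    """
    optimizer = SGD(model.parameters(), config.lr, config.weight_decay,
                    config.momentum)
    scheduler = ReduceLROnPlateau(optimizer, config.lr_factor,
                                  config.scheduler_patience)
    stopper = EarlyStopping(config.early_stop_patience)
    history = History()
    best_val = math.inf
    best_state = None

    for epoch in range(config.max_epochs):
        model.train()
        total, correct, loss_sum = 0, 0, 0.0
        for x, y in train_stream.batches(config.batch_size, epoch_index=epoch):
            optimizer.zero_grad()
            logits = model(Tensor(x))
            loss = ad.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            loss.backward()
            optimizer.step()
            loss_sum += float(loss.data) * len(y)
            correct += int((logits.data.argmax(axis=1) == y).sum())
            total += len(y)
        train_loss, train_acc = loss_sum / total, correct / total
        val_loss, val_acc = evaluate_loss(model, val_stream.batches(config.batch_size))
        history.append(EpochRecord(epoch, train_loss, train_acc, val_loss,
                                   val_acc, optimizer.lr))
        if verbose:
            print(f"epoch {epoch}: train loss {train_loss:.4f} acc {train_acc:.3f} "
                  f"| val loss {val_loss:.4f} acc {val_acc:.3f} | lr {optimizer.lr:g}")
        if val_loss < best_val - IMPROVEMENT_TOL:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        scheduler.step(val_loss)
        if stopper.step(val_loss):
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        history.to_csv(out_dir / "history.csv")
        model.save(out_dir / "checkpoint.npz")
        (out_dir / "run.json").write_text(json.dumps({
            "config": asdict(config),
            "epochs_run": len(history),
            "best_val_loss": best_val,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }, indent=2))
    return model, history
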