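"""Losses, task-homogeneous batch sampling, early-stopped Adam training,
and randomized hyperparameter search.

The multitask loss gates on the batch's task: a methylation batch
contributes γ·L_CE, any other task contributes plain L_CE, and the three
inactive heads receive no gradient at all (partial parameter sharing). The
γ up-weighting compensates for methylation sites being vastly outnumbered
by the other PTM instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from . import nn
from .embeddings import EmbeddedWindow
from .evaluation import pr_roc_curves
from .models import TransformerModel
from .records import ValidationError

#: Probabilities are clamped here before logarithms.
SCORE_CLAMP = 1e-12


@dataclass
class TaskBatch:
    """A homogeneous-task minibatch: the unit over which the loss is taken."""

    tokens: np.ndarray        # (N, context, d)
    masks: np.ndarray         # (N, context)
    labels: np.ndarray        # (N,)
    task: str

    def __post_init__(self) -> None:
        if self.tokens.shape[0] < 1:
            raise ValidationError("batch must contain at least one instance")

    @property
    def size(self) -> int:
        return self.tokens.shape[0]


@dataclass(frozen=True)
class MultitaskLossConfig:
    """γ-weighting of the methylation loss.

    The candidates mirror the searched grid: 1 (no weighting), 13.5
    (approximately the methylation-to-other-PTM instance ratio), and 20
    (the shipped value).
    """

    gamma: float = 20.0
    candidate_gammas: tuple[float, ...] = (1.0, 13.5, 20.0)

    def __post_init__(self) -> None:
        if self.gamma < 1.0:
            raise ValidationError(f"gamma must be >= 1, got {self.gamma}")


def bce_loss(scores: Sequence[float] | np.ndarray,
             labels: Sequence[int] | np.ndarray) -> float:
    """Mean binary cross-entropy −(1/N)·Σ[y·log ŷ + (1−y)·log(1−ŷ)]."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if s.size == 0:
        raise ValidationError("empty input to bce_loss")
    if s.shape != y.shape:
        raise ValidationError(f"shape mismatch: {s.shape} vs {y.shape}")
    s = np.clip(s, SCORE_CLAMP, 1.0 - SCORE_CLAMP)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def multitask_batch_loss(batch: TaskBatch,
                         scores: Sequence[float] | np.ndarray,
                         config: MultitaskLossConfig) -> float:
    """γ·L_CE for methylation batches, plain L_CE otherwise.

    Other tasks' contributions are exactly zero for this batch by
    construction (their heads are never evaluated).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != batch.size:
        raise ValidationError(
            f"{scores.shape[0]} scores for a batch of {batch.size}"
        )
    base = bce_loss(scores, batch.labels)
    return config.gamma * base if batch.task == "methylation" else base


def task_batch_sampler(
    datasets: Mapping[str, Sequence[EmbeddedWindow]],
    batch_size: int,
    seed: int = 0,
) -> Iterator[TaskBatch]:
    """One epoch of homogeneous-task batches.

    Each task's instances are shuffled and chunked; the resulting batches
    are then shuffled globally, which interleaves tasks in proportion to
    their dataset sizes. Every instance appears exactly once; final partial
    batches are kept. A declared-but-empty task simply emits nothing.
    """
    if batch_size < 1:
        raise ValidationError(f"batch_size must be >= 1, got {batch_size}")
    rng = np.random.default_rng(seed)
    chunks: list[tuple[str, np.ndarray]] = []
    for task in sorted(datasets):
        n = len(datasets[task])
        if n == 0:
            continue
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            chunks.append((task, order[start:start + batch_size]))
    rng.shuffle(chunks)
    for task, idx in chunks:
        items = [datasets[task][i] for i in idx]
        yield TaskBatch(
            tokens=np.stack([w.tokens for w in items]),
            masks=np.stack([w.mask for w in items]),
            labels=np.array([w.label for w in items], dtype=np.float64),
            task=task,
        )


@dataclass
class TrainState:
    """Outcome of an early-stopped fit: best-epoch parameters and metrics."""

    epoch: int
    best_validation_loss: float
    best_validation_auprc: float
    patience_counter: int
    parameters: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)


def _as_batch_arrays(
    windows: Sequence[EmbeddedWindow],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        np.stack([w.tokens for w in windows]),
        np.stack([w.mask for w in windows]),
        np.array([w.label for w in windows], dtype=np.float64),
    )


def evaluate_model(model: TransformerModel,
                   windows: Sequence[EmbeddedWindow],
                   task: str = "methylation",
                   batch_size: int = 256) -> tuple[float, float]:
    """(BCE loss, AUPRC) of a model on a window set, evaluation mode."""
    tokens, masks, labels = _as_batch_arrays(windows)
    scores = np.concatenate([
        model.score(tokens[i:i + batch_size], masks[i:i + batch_size],
                    task=task if model.head_spec is not None else None)
        for i in range(0, len(windows), batch_size)
    ])
    curves = pr_roc_curves(scores, labels)
    return bce_loss(scores, labels), curves.auprc


def fit_early_stopping(
    model: TransformerModel,
    train_datasets: Mapping[str, Sequence[EmbeddedWindow]],
    validation: Sequence[EmbeddedWindow],
    learning_rate: float = 1e-3,
    gamma: float = 20.0,
    batch_size: int = 128,
    patience: int = 10,
    max_epochs: int = 100,
    seed: int = 0,
    monitor_task: str = "methylation",
) -> TrainState:
    """Adam training with task-homogeneous batches and early stopping.

    After each epoch, validation BCE loss and AUPRC are computed on the
    monitor task (methylation by default). The parameters of the best
    validation-loss epoch are retained; training stops after ``patience``
    epochs without improvement or at ``max_epochs``. For a methylation
    batch the per-instance gradient is scaled by γ.
    """
    if not validation:
        raise ValidationError("validation set must be nonempty")
    loss_cfg = MultitaskLossConfig(gamma=gamma)
    opt = nn.Adam(lr=learning_rate)
    drop_rng = np.random.default_rng([seed, 0x5D])
    single = model.head_spec is None

    best = TrainState(
        epoch=0, best_validation_loss=math.inf, best_validation_auprc=0.0,
        patience_counter=0, parameters=model.state_dict(), history=[],
    )
    for epoch in range(1, max_epochs + 1):
        epoch_loss, n_batches = 0.0, 0
        for batch in task_batch_sampler(train_datasets, batch_size,
                                        seed=seed * 10007 + epoch):
            head_task = None if single else batch.task
            logits = model.forward(batch.tokens, batch.masks, task=head_task,
                                   train=True, rng=drop_rng)
            probs = nn.sigmoid(logits)
            loss = multitask_batch_loss(batch, probs, loss_cfg)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss {loss}"
                )
            weight = loss_cfg.gamma if batch.task == "methylation" else 1.0
            dlogits = weight * (probs - batch.labels) / batch.size
            params = model.trunk_params() + model.head_params(head_task)
            opt.zero_grad(params)
            model.backward(dlogits)
            opt.step(params)
            epoch_loss += loss
            n_batches += 1

        val_loss, val_auprc = evaluate_model(
            model, validation,
            task=monitor_task if not single else "methylation",
        )
        best.history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "validation_loss": val_loss,
            "validation_auprc": val_auprc,
        })
        if val_loss < best.best_validation_loss:
            best.best_validation_loss = val_loss
            best.best_validation_auprc = val_auprc
            best.epoch = epoch
            best.parameters = model.state_dict()
            best.patience_counter = 0
        else:
            best.patience_counter += 1
            if best.patience_counter > patience:
                break
    model.load_state_dict(best.parameters)
    return best


@dataclass(frozen=True)
class HyperparameterSpace:
    """Ranges sampled uniformly (learning rate log-uniformly) per trial."""

    learning_rate: tuple[float, float] = (1e-5, 1e-2)
    n_hidden_layers: tuple[int, int] = (1, 3)
    layer_width: tuple[int, int] = (16, 256)
    dropout: tuple[float, float] = (0.0, 0.5)
    n_blocks: tuple[int, int] = (1, 2)
    embed_width: tuple[int, int] = (16, 64)
    n_trials: int = 50

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = self.learning_rate
        return {
            "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "n_hidden_layers": int(rng.integers(self.n_hidden_layers[0],
                                                self.n_hidden_layers[1] + 1)),
            "layer_width": int(rng.integers(self.layer_width[0],
                                            self.layer_width[1] + 1)),
            "dropout": float(rng.uniform(*self.dropout)),
            "n_blocks": int(rng.integers(self.n_blocks[0],
                                         self.n_blocks[1] + 1)),
            "embed_width": int(2 * rng.integers(self.embed_width[0] // 2,
                                                self.embed_width[1] // 2 + 1)),
        }


def random_search(
    space: HyperparameterSpace,
    objective: Callable[[dict], float],
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """n_trials independent draws; returns the argmax-AUPRC configuration
    and the full trial log. Failed trials are logged, not fatal — unless
    every trial fails."""
    rng = np.random.default_rng([seed, 0x0B])
    trials: list[dict] = []
    best_cfg, best_val = None, -math.inf
    for i in range(space.n_trials):
        cfg = space.sample(rng)
        try:
            value = float(objective(cfg))
            trials.append({"trial": i, "config": cfg, "auprc": value})
            if value > best_val:
                best_cfg, best_val = cfg, value
        except Exception as exc:  # noqa: BLE001 - logged per trial
            trials.append({"trial": i, "config": cfg, "error": repr(exc)})
    if best_cfg is None:
        raise RuntimeError(f"all {space.n_trials} trials failed: {trials}")
    return best_cfg, trials
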