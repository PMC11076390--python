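"""Training, evaluation and experiment configuration.

Optimization follows the reference recipe: Adam (beta1 = 0.9), initial
learning rate 1e-4 decayed to a minimum of 1e-5 (cosine annealing over
the epochs — the schedule family is a package choice, pinned by its two
endpoints), weight decay 1e-4, batch size 4, validation every epoch, and
best-checkpoint selection by validation DSC.  The loss is the combined
0.5*BCE + Dice objective.  All randomness (shuffling, augmentation draws)
derives from ``TrainConfig.seed``, so runs are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor, sigmoid
from .objectives import combined_loss, confusion, metrics, ConfusionCounts
from .preprocessing import SliceSample, augment

logger = logging.getLogger("asdnet")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    batch_size: int = 4
    epochs: int = 100
    initial_lr: float = 1e-4
    min_lr: float = 1e-5
    beta1: float = 0.9          # Adam first-moment coefficient ("momentum")
    weight_decay: float = 1e-4
    validate_every: int = 1
    threshold: float = 0.5
    augment: bool = True        # flip/rotate augmentation on the training split
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_lr <= self.initial_lr:
            raise ValueError("require 0 < min_lr <= initial_lr")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dsc: float = -1.0

    def to_frame(self) -> "pandas.DataFrame":
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss, "val_loss": self.val_loss,
            "val_dsc": self.val_dsc, "val_iou": self.val_iou, "lr": self.lr,
        })


def _stack(samples: Sequence[SliceSample]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    masks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return imgs, masks


def train_step(model: nn.Module, optimizer: nn.Adam, images: np.ndarray,
               masks: np.ndarray) -> float:
    """One optimisation step on a batch; returns the batch loss."""
    optimizer.zero_grad()
    logits = model(Tensor(images))
    loss = combined_loss(sigmoid(logits), masks)
    value = float(loss.data)
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged: loss = {value}")
    loss.backward()
    optimizer.step()
    return value


def train(model: nn.Module, train_samples: Sequence[SliceSample],
          val_samples: Sequence[SliceSample],
          config: TrainConfig = TrainConfig()) -> tuple[TrainHistory, dict]:
    """Optimise the combined loss; returns history and the best state dict
    (selected by validation DSC, ties resolved to the earlier epoch)."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.initial_lr,
                        betas=(config.beta1, 0.999),
                        weight_decay=config.weight_decay)
    history = TrainHistory()
    best_state = model.state_dict()
    val_loss = float("nan")
    agg = {"dsc": float("nan"), "iou": float("nan")}

    for epoch in range(config.epochs):
        lr = nn.cosine_lr(epoch, config.epochs, config.initial_lr, config.min_lr)
        optimizer.lr = lr
        model.train()
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_samples[i] for i in idx]
            if config.augment:
                batch = [augment(s, int(rng.integers(2 ** 31))) for s in batch]
            images, masks = _stack(batch)
            losses.append(train_step(model, optimizer, images, masks))
        train_loss = float(np.mean(losses))

        did_validate = ((epoch + 1) % config.validate_every == 0
                        or epoch == config.epochs - 1)
        if did_validate:
            val_loss, agg = _validate(model, val_samples, config)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.val_dsc.append(agg["dsc"])
        history.val_iou.append(agg["iou"])
        history.lr.append(lr)
        if did_validate and agg["dsc"] > history.best_val_dsc:
            history.best_val_dsc = agg["dsc"]
            history.best_epoch = epoch
            best_state = model.state_dict()
        logger.info("epoch %d lr %.2e train_loss %.4f val_loss %.4f val_dsc %.4f",
                    epoch, lr, train_loss, val_loss, agg["dsc"])
    return history, best_state


def _validate(model: nn.Module, samples: Sequence[SliceSample],
              config: TrainConfig) -> tuple[float, dict]:
    model.eval()
    losses = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    with nn.no_grad():
        for start in range(0, len(samples), config.batch_size):
            batch = samples[start:start + config.batch_size]
            images, masks = _stack(batch)
            logits = model(Tensor(images))
            probs = sigmoid(logits)
            losses.append(float(combined_loss(probs, masks).data))
            pred = (probs.data >= config.threshold).astype(np.uint8)
            pooled = pooled + confusion(pred, masks.astype(np.uint8))
    return float(np.mean(losses)), metrics(pooled)


def evaluate(model: nn.Module, samples: Sequence[SliceSample],
             threshold: float = 0.5) -> tuple["pandas.DataFrame", dict]:
    """Per-slice metric table plus aggregates.

    Aggregates are reported two ways: ``pooled`` (metrics of the summed
    confusion counts over all test pixels) and ``mean`` (per-slice metric
    averages).
    """
    import pandas as pd
    from .network import predict_mask

    if not samples:
        raise ValueError("empty test set")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for s in samples:
        pred = predict_mask(model, s.image, threshold)
        c = confusion(pred, s.mask)
        pooled = pooled + c
        rows.append({"case_id": s.case_id, "slice_index": s.slice_index,
                     "task": s.task, **metrics(c)})
    table = pd.DataFrame(rows)
    aggregate = {
        "pooled": metrics(pooled),
        "mean": {k: float(table[k].mean())
                 for k in ("iou", "dsc", "recall", "precision")},
    }
    return table, aggregate
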