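"""Training losses and segmentation evaluation metrics.

The training objective is a compound of pixel-wise binary cross-entropy
and soft Dice,

    L = 0.5 * L_BCE + L_Dice,

which balances per-pixel classification accuracy against region overlap
and behaves well under the heavy foreground/background imbalance typical
of tumor slices.  Evaluation uses the four standard overlap metrics
(IoU, DSC, recall, precision) computed from pixel confusion counts.

Losses accept either plain numpy arrays (returning a float) or autograd
tensors (returning a differentiable scalar tensor), so the same code path
serves both unit arithmetic and network training.

Conventions:

* BCE is the per-element mean (not the raw sum), so the loss scale does
  not depend on image resolution.
* Dice is computed per sample and averaged over the batch; arrays of
  rank >= 3 are treated as batches along axis 0, lower ranks as a single
  sample.
* Dice smoothing: eps = 1e-6 added to numerator and denominator, so a
  sample where prediction and ground truth are both empty contributes
  loss 0 (perfect agreement) instead of being undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

BCE_CLAMP_EPS = 1e-7
DICE_EPS = 1e-6


def _prepare(p, y) -> tuple[Tensor, np.ndarray, bool]:
    was_tensor = isinstance(p, Tensor)
    pt = p if was_tensor else Tensor(np.asarray(p, dtype=np.float64))
    ya = y.data if isinstance(y, Tensor) else np.asarray(y)
    if pt.data.shape != ya.shape:
        raise ValueError(f"shape mismatch: p {pt.data.shape} vs y {ya.shape}")
    if not was_tensor:
        if np.any((pt.data < 0) | (pt.data > 1)):
            raise ValueError("predicted probabilities must lie in [0, 1]")
        if not np.isin(ya, (0, 1)).all():
            raise ValueError("labels must be binary")
    return pt, ya.astype(np.float64), was_tensor


def bce_loss(p, y):
    """Mean binary cross-entropy  -mean[y ln p + (1-y) ln(1-p)].

    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logarithms.
    """
    pt, ya, was_tensor = _prepare(p, y)
    pc = nn.clip(pt, BCE_CLAMP_EPS, 1.0 - BCE_CLAMP_EPS)
    loss = -(ya * nn.log(pc) + (1.0 - ya) * nn.log(1.0 - pc)).mean()
    return loss if was_tensor else float(loss.data)


def dice_loss(p, y):
    """Soft Dice loss  1 - (2 sum(y*p) + eps) / (sum(y^2) + sum(p^2) + eps).

    Computed per sample (batch axis 0 for rank >= 3 input) and averaged.
    """
    pt, ya, was_tensor = _prepare(p, y)
    if pt.data.ndim >= 3:
        n = pt.data.shape[0]
        pf = pt.reshape(n, -1)
        yf = ya.reshape(n, -1)
        axis = 1
    else:
        pf = pt.reshape(1, -1)
        yf = ya.reshape(1, -1)
        axis = 1
    num = 2.0 * (pf * yf).sum(axis=axis) + DICE_EPS
    den = (yf * yf).sum(axis=axis) + (pf * pf).sum(axis=axis) + DICE_EPS
    loss = (1.0 - num * den ** -1.0).mean()
    return loss if was_tensor else float(loss.data)


def combined_loss(p, y):
    """Compound objective 0.5 * BCE + Dice."""
    b = bce_loss(p, y)
    d = dice_loss(p, y)
    if isinstance(b, Tensor):
        return 0.5 * b + d
    return 0.5 * b + d


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Exact TP/FP/FN/TN pixel counts for two binary masks of equal shape."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not np.isin(p, (0, 1)).all() or not np.isin(t, (0, 1)).all():
        raise ValueError("masks must be binary (values in {0, 1})")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio(num: int, den: int, counts: ConfusionCounts) -> float:
    if den == 0:
        # undefined denominator: score 1.0 only in the all-agree empty case
        return 1.0 if (counts.tp + counts.fp + counts.fn) == 0 else 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """IoU, DSC, recall and precision from confusion counts.

    IoU = TP/(TP+FP+FN); DSC = 2TP/(2TP+FP+FN); Recall = TP/(TP+FN);
    Precision = TP/(TP+FP).  When prediction and ground truth are both
    empty every metric is reported as 1.0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    return {
        "iou": _ratio(tp, tp + fp + fn, counts),
        "dsc": _ratio(2 * tp, 2 * tp + fp + fn, counts),
        "recall": _ratio(tp, tp + fn, counts),
        "precision": _ratio(tp, tp + fp, counts),
    }
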