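"""Combined soft-Dice + cross-entropy segmentation loss.

The Dice term is the soft relaxation of ``1 − 2TP/(2TP+FP+FN)``: true/false
positives/negatives are accumulated from class probabilities against one-hot
targets, per class (background included by default) and per sample, then
averaged.  The cross-entropy term is the mean negative log-probability of the
true class over all pixels.  The combined loss is their exact sum.

All three functions accept either autodiff tensors (used inside the training
loop) or plain NumPy probability arrays, and a ``(B,K,H,W)`` probability
array against a ``(B,H,W)`` integer label mask (leading batch axis optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, tlog, tmean, tsum
from .nn.tensor import getitem

SMOOTH = 1e-5
LOG_CLIP = 1e-12


@dataclass
class LossValue:
    dice: float
    ce: float

    @property
    def total(self) -> float:
        return self.dice + self.ce


def _prep(probs, target, num_classes=None):
    probs_t = as_tensor(probs)
    if probs_t.ndim == 3:  # single image K,H,W
        probs_t = probs_t.reshape((1,) + tuple(probs_t.shape))
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    k = probs_t.shape[1]
    if target.max(initial=0) >= k:
        raise ValueError(
            f"target contains label {int(target.max())} but probabilities have "
            f"only {k} classes"
        )
    if target.shape != (probs_t.shape[0],) + tuple(probs_t.shape[2:]):
        raise ValueError(
            f"target shape {target.shape} does not match probabilities {probs_t.shape}"
        )
    onehot = np.zeros(probs_t.shape, dtype=probs_t.dtype)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    return probs_t, target, onehot


def dice_loss(probs, target, include_background: bool = True):
    """1 − mean soft-Dice over classes and batch (smoothing 1e-5).

    For each sample and class, soft TP = Σ p·t, and 2TP+FP+FN = Σp + Σt, so
    the class Dice is (2Σp·t + s) / (Σp + Σt + s).
    """
    probs_t, _, onehot = _prep(probs, target)
    inter = tsum(probs_t * Tensor(onehot), axis=(2, 3))     # B,K
    sums = tsum(probs_t, axis=(2, 3)) + onehot.sum(axis=(2, 3))
    dice = (2.0 * inter + SMOOTH) / (sums + SMOOTH)
    if not include_background:
        dice = getitem(dice, (slice(None), slice(1, None)))
    loss = 1.0 - tmean(dice)
    return loss if isinstance(probs, Tensor) else float(loss.item())


def cross_entropy_loss(probs, target):
    """−mean log p(true class); probabilities clipped below at 1e-12."""
    probs_t, target, onehot = _prep(probs, target)
    p_true = tsum(probs_t * Tensor(onehot), axis=1)  # B,H,W
    clipped = p_true + (p_true.data < LOG_CLIP) * LOG_CLIP  # keeps graph intact
    loss = -tmean(tlog(clipped))
    return loss if isinstance(probs, Tensor) else float(loss.item())


def total_loss(probs, target, include_background: bool = True):
    """Dice + cross-entropy.  Returns (LossValue, total) for tensors, where
    ``total`` is the differentiable sum; a plain LossValue otherwise."""
    d = dice_loss(probs, target, include_background)
    c = cross_entropy_loss(probs, target)
    if isinstance(probs, Tensor):
        return LossValue(dice=float(d.item()), ce=float(c.item())), d + c
    return LossValue(dice=d, ce=c)
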