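"""Training losses: focal, soft dice, and their sum.

The focal loss is the standard form ``-alpha_c (1 - p_t)^gamma log(p_t)``
averaged over pixels, where ``p_t`` is the predicted probability of the
pixel's true class ``c`` and ``alpha_c`` folds the mean-one class weight
into the alpha factor; gamma down-weights easy pixels so training
concentrates on hard ones.  The soft dice coefficient for one class is
``2 sum(p g) / (sum(p^2) + sum(g^2))`` over pixels, smoothed by a small
epsilon and averaged over the classes present in the ground truth; the
dice loss is one minus that.  The combined objective is the unweighted sum
of the two terms: it is non-negative and zero exactly at a perfect
(pre-clipping) prediction.

All functions take a probability map ``(H, W, C)`` and an integer label
mask ``(H, W)``; ``*_grad`` variants also return the gradient with respect
to the probabilities, which the trainer chains through the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ClassWeights

__all__ = ["FocalParams", "focal_loss", "dice_coefficient", "dice_loss",
           "combined_loss", "focal_loss_grad", "dice_loss_grad",
           "combined_loss_grad"]

_EPS_CLIP = 1e-7
_EPS_DICE = 1e-6


@dataclass(frozen=True)
class FocalParams:
    """alpha: base weighting factor (> 0); gamma: focusing exponent (>= 0)."""

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def _check(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.ndim != 3:
        raise ValueError("pred must be (H, W, C)")
    if truth.shape != pred.shape[:2]:
        raise ValueError(f"shape mismatch: pred {pred.shape[:2]} vs truth "
                         f"{truth.shape}")
    if pred.min() < -1e-6 or pred.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    if truth.min() < 0 or truth.max() >= pred.shape[2]:
        raise ValueError("mask labels outside [0, n_classes)")
    return pred, truth.astype(np.int64)


def _alphas(params: FocalParams, class_weights: ClassWeights | None,
            n_classes: int) -> np.ndarray:
    a = np.full(n_classes, params.alpha, dtype=np.float64)
    if class_weights is not None:
        w = class_weights.as_array()
        if w.size != n_classes:
            raise ValueError("class weight length does not match n_classes")
        a = a * w
    return a


def focal_loss(pred: np.ndarray, truth: np.ndarray,
               params: FocalParams = FocalParams(),
               class_weights: ClassWeights | None = None) -> float:
    loss, _ = focal_loss_grad(pred, truth, params, class_weights)
    return loss


def focal_loss_grad(pred, truth, params: FocalParams = FocalParams(),
                    class_weights: ClassWeights | None = None):
    """Return ``(loss, dloss/dpred)``; the gradient is zero off the true class."""
    pred, truth = _check(pred, truth)
    h, w, c = pred.shape
    alphas = _alphas(params, class_weights, c)[truth]          # (H, W)
    pt = np.take_along_axis(pred, truth[..., None], axis=2)[..., 0]
    pt = np.clip(pt, _EPS_CLIP, 1.0 - _EPS_CLIP)
    onem = 1.0 - pt
    g = params.gamma
    per_px = -alphas * onem ** g * np.log(pt)
    loss = float(per_px.mean())
    # d/dp [ -a (1-p)^g log p ] = a [ g (1-p)^(g-1) log p - (1-p)^g / p ]
    dpt = alphas * (g * onem ** (g - 1) * np.log(pt) - onem ** g / pt) if g > 0 \
        else -alphas / pt
    grad = np.zeros_like(pred)
    np.put_along_axis(grad, truth[..., None], (dpt / (h * w))[..., None], axis=2)
    return loss, grad


def _one_hot(truth: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float64)[truth]


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Soft dice averaged over classes present in the ground truth."""
    d, _ = _dice(pred, truth)
    return d


def _dice(pred, truth):
    pred, truth = _check(pred, truth)
    g = _one_hot(truth, pred.shape[2])
    present = np.nonzero(g.sum(axis=(0, 1)) > 0)[0]
    num = 2.0 * (pred * g).sum(axis=(0, 1)) + _EPS_DICE
    den = (pred ** 2).sum(axis=(0, 1)) + g.sum(axis=(0, 1)) + _EPS_DICE
    per_class = num / den
    d = float(per_class[present].mean())
    # gradient of mean-over-present-classes dice w.r.t. pred
    grad = np.zeros_like(pred)
    for c in present:
        grad[..., c] = (2.0 * g[..., c] * den[c] - num[c] * 2.0 * pred[..., c]) \
            / den[c] ** 2
    grad /= len(present)
    return d, grad


def dice_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    return 1.0 - dice_coefficient(pred, truth)


def dice_loss_grad(pred, truth):
    d, grad = _dice(pred, truth)
    return 1.0 - d, -grad


def combined_loss(pred, truth, params: FocalParams = FocalParams(),
                  class_weights: ClassWeights | None = None,
                  include_dice: bool = True) -> float:
    """Focal + dice with unit weights (``include_dice=False`` isolates the
    focal term for diagnostics)."""
    loss, _ = combined_loss_grad(pred, truth, params, class_weights,
                                 include_dice=include_dice)
    return loss


def combined_loss_grad(pred, truth, params: FocalParams = FocalParams(),
                       class_weights: ClassWeights | None = None,
                       include_dice: bool = True):
    fl, fg = focal_loss_grad(pred, truth, params, class_weights)
    if not include_dice:
        return fl, fg
    dl, dg = dice_loss_grad(pred, truth)
    return fl + dl, fg + dg
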