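"""Grad-CAM class-discriminative saliency at the U-Net bottleneck.

For a target class ``c``, the class score ``Y^c`` is the spatial sum of
the pre-softmax class-c logits over all output pixels (the standard dense-
prediction extension of the classification score).  Each bottleneck filter
``k`` receives the weight ``w_k^c = (1/Z) sum_ij dY^c / dA^k_ij`` — the
global average of the gradient over the Z spatial positions of the
bottleneck map — and the saliency map is ``ReLU(sum_k w_k^c A^k)``,
bilinearly resampled to the input size and min-max normalized to [0, 1]
(an all-zero map stays all-zero).  The bottleneck is used because the
deepest encoder activations are the most semantically informative layer
of a U-Net; any other layer can be selected by node name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .zoo import BaseLearner

__all__ = ["ActivationStack", "SaliencyMap", "class_score", "gradcam_map",
           "overlay_heatmap"]


@dataclass
class ActivationStack:
    """Bottleneck activations A^k with the gradients dY^c/dA^k."""

    activations: np.ndarray  # (K, h, w)
    gradients: np.ndarray    # (K, h, w)

    @property
    def Z(self) -> int:
        return int(self.activations.shape[1] * self.activations.shape[2])


@dataclass
class SaliencyMap:
    """Non-negative class saliency aligned with the input image."""

    values: np.ndarray  # (H, W) in [0, 1]
    class_id: int
    layer_name: str


def _target_node(learner: BaseLearner, layer_name: str | None) -> nn.Node:
    if layer_name is None:
        return learner.bottleneck
    return learner.model.get_node(layer_name)


def class_score(learner: BaseLearner, image: np.ndarray, class_id: int,
                layer_name: str | None = None) -> tuple[float, ActivationStack]:
    """Compute Y^c and record the target layer's activations/gradients."""
    if not 0 <= class_id < learner.n_classes:
        raise ValueError(f"class_id must lie in [0, {learner.n_classes})")
    target = _target_node(learner, layer_name)
    # view of the graph ending at the raw logits (pre-softmax)
    logits_model = nn.Model(learner.model.input, learner.logits)
    x = learner.prepare_input(image)
    logits, ctx = logits_model.forward(x, record=True)
    y_c = float(logits[class_id].sum())
    grad_out = np.zeros_like(logits)
    grad_out[class_id] = 1.0
    logits_model.zero_grad()
    res = logits_model.backward(grad_out, ctx, capture=target)
    logits_model.zero_grad()  # discard parameter grads from this probe
    acts = ctx["values"][id(target)]
    grads = res["captured"]
    if grads is None:  # target not on the path to the logits
        grads = np.zeros_like(acts)
    return y_c, ActivationStack(np.asarray(acts), np.asarray(grads))


def gradcam_map(learner: BaseLearner, image: np.ndarray, class_id: int,
                layer_name: str | None = None) -> SaliencyMap:
    """ReLU of the gradient-weighted activation sum, resampled and
    normalized to the input frame."""
    _, stack = class_score(learner, image, class_id, layer_name)
    w = stack.gradients.mean(axis=(1, 2))            # (K,) global-average grads
    cam = np.einsum("k,kij->ij", w, stack.activations)
    cam = np.maximum(cam, 0.0)
    h, w_in = np.asarray(image).shape[:2]
    if cam.shape != (h, w_in):
        zoom = (h / cam.shape[0], w_in / cam.shape[1])
        cam = ndimage.zoom(cam, zoom, order=1, mode="nearest", grid_mode=True)
        cam = np.maximum(cam[:h, :w_in], 0.0)
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    name = layer_name if layer_name is not None else learner.bottleneck.name
    return SaliencyMap(cam.astype(np.float32), class_id, name)


def overlay_heatmap(image: np.ndarray, saliency: SaliencyMap,
                    alpha: float = 0.4) -> np.ndarray:
    """Blend a blue-to-red heat map of the saliency over the (grayscale)
    image; returns uint8 RGB of the input size."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.shape != saliency.values.shape:
        raise ValueError("image and saliency map shapes disagree")
    rng = img.max() - img.min()
    gray = (img - img.min()) / rng if rng > 0 else np.zeros_like(img)
    base = np.stack([gray] * 3, axis=2)
    from matplotlib import colormaps
    heat = colormaps["jet"](saliency.values.astype(np.float64))[..., :3]
    out = (1.0 - alpha) * base + alpha * heat
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)
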