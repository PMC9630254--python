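"""U-Net base-learners with interchangeable classification-backbone encoders.

A base-learner is a U-Net whose encoder is one of the registered backbones
(ResNet34, InceptionV3, VGG19, SeResNet34, EfficientNet-B4 form the default
ensemble pool; ResNet18, VGG16, EfficientNet-B0 are the small-study
variants; ``tiny`` is a lightweight non-pretrained encoder for phantom-scale
work).  The decoder has five upsampling stages (default filter widths
256/128/64/32/16), each an upsample -> concatenate-long-skip -> two
conv-BN-ReLU block, closed by a 3x3 convolution and a per-pixel softmax
over the segmentation classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .. import nn
from .encoders import ENCODERS, EncoderDef

__all__ = ["EncoderSpec", "BaseLearner", "list_encoders", "build_base_learner",
           "count_parameters", "save_checkpoint", "load_checkpoint",
           "DEFAULT_ENSEMBLE"]

DEFAULT_ENSEMBLE = ("resnet34", "inceptionv3", "vgg19", "seresnet34",
                    "efficientnetb4")


@dataclass(frozen=True)
class EncoderSpec:
    """Descriptor of a registered encoder backbone."""

    name: str
    has_short_skips: bool
    stage_output_names: tuple[str, ...]
    in_default_ensemble: bool

    @staticmethod
    def from_def(d: EncoderDef, stage_names: tuple[str, ...] = ()) -> "EncoderSpec":
        return EncoderSpec(d.name, d.has_short_skips, stage_names,
                           d.in_default_ensemble)


@dataclass
class BaseLearner:
    """A built U-Net: the executable model plus its accounting metadata."""

    encoder: EncoderSpec
    n_classes: int
    model: nn.Model
    bottleneck: nn.Node
    logits: nn.Node
    pretrained: bool
    input_channels: int
    normalization: str
    trainable_params: int = 0
    nontrainable_params: int = 0
    total_params: int = 0

    def __post_init__(self):
        tr, ntr, tot = self.model.count_params()
        self.trainable_params, self.nontrainable_params, self.total_params = tr, ntr, tot

    # -- inference ----------------------------------------------------------
    def prepare_input(self, image: np.ndarray) -> np.ndarray:
        """Normalize an (H, W) or (H, W, C) image into the network layout."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = img[None]
        elif img.ndim == 3:
            img = img.transpose(2, 0, 1)
        else:
            raise ValueError("image must be 2-D or (H, W, C)")
        if img.shape[0] == 1 and self.input_channels > 1:
            img = np.repeat(img, self.input_channels, axis=0)
        if img.shape[0] != self.input_channels:
            raise ValueError(f"expected {self.input_channels} channels, got {img.shape[0]}")
        if img.shape[1] % 32 or img.shape[2] % 32:
            raise ValueError("input height and width must be divisible by 32")
        if self.normalization == "minmax":
            lo, hi = img.min(), img.max()
            img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        else:  # imagenet-style
            img = img / 255.0
            mean = np.array([0.485, 0.456, 0.406], np.float32)[:, None, None]
            std = np.array([0.229, 0.224, 0.225], np.float32)[:, None, None]
            img = (img - mean) / std
        return img.astype(np.float32)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities, shape (H, W, n_classes)."""
        out = self.model.forward(self.prepare_input(image), training=False)
        return out.transpose(1, 2, 0)

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        """Hard argmax mask (ties resolved toward the lower class index)."""
        return self.predict_proba(image).argmax(axis=2).astype(np.int32)


def list_encoders(ensemble_only: bool = False) -> list[EncoderSpec]:
    """Deterministic registry of available encoders."""
    specs = [EncoderSpec.from_def(d) for d in ENCODERS.values()]
    if ensemble_only:
        specs = [s for s in specs if s.in_default_ensemble]
    return specs


def _unet_decoder(x, skips, filters, n_classes, rng):
    for i, f in enumerate(filters):
        x = nn.UpSampling2D(2)(x)
        if i < len(skips):
            x = nn.Concatenate()([x, skips[i]])
        for _ in range(2):
            x = nn.Conv2D(f, 3, use_bias=False, rng=rng)(x)
            x = nn.BatchNorm()(x)
            x = nn.Activation("relu")(x)
    logits = nn.Conv2D(n_classes, 3, use_bias=True, rng=rng, name="final_conv")(x)
    probs = nn.Activation("softmax", name="softmax")(logits)
    return logits, probs


def build_base_learner(encoder_name: str, n_classes: int, pretrained: bool = False,
                       input_channels: int = 3, seed: int = 0,
                       decoder_filters: tuple[int, ...] | None = None,
                       bottleneck_channels: int | None = None,
                       weights_path: str | Path | None = None) -> BaseLearner:
    """Build a U-Net base-learner around a named encoder.

    ``bottleneck_channels`` optionally inserts an extra conv-BN-ReLU block of
    that width between encoder and decoder; by default the encoder's deepest
    activation itself is the bottleneck, which is the configuration whose
    parameter totals match the published accounting for these backbones.
    With ``pretrained=False`` weights are He-initialized from ``seed`` and no
    file or network access happens; ``pretrained=True`` requires a local
    checkpoint via ``weights_path``.
    """
    if encoder_name not in ENCODERS:
        raise KeyError(f"unknown encoder {encoder_name!r}; choose from "
                       f"{sorted(ENCODERS)}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    edef = ENCODERS[encoder_name]
    if pretrained and weights_path is None:
        raise RuntimeError(
            "pretrained=True needs a local checkpoint (weights_path=...); "
            "this build never downloads weights")
    rng = np.random.default_rng(seed)
    inp = nn.Input(input_channels)
    x, skips = edef.builder(inp, rng)
    bottleneck = x
    if bottleneck_channels:
        x = nn.Conv2D(bottleneck_channels, 3, use_bias=False, rng=rng,
                      name="extra_bottleneck")(x)
        x = nn.BatchNorm()(x)
        x = nn.Activation("relu")(x)
        bottleneck = x
    filters = tuple(decoder_filters) if decoder_filters else edef.decoder_filters
    if len(filters) != 5:
        raise ValueError("decoder needs exactly five upsampling stages")
    logits, probs = _unet_decoder(x, skips, filters, n_classes, rng)
    model = nn.Model(inp, probs)
    learner = BaseLearner(
        encoder=EncoderSpec.from_def(edef, tuple(s.name for s in skips)),
        n_classes=n_classes, model=model, bottleneck=bottleneck, logits=logits,
        pretrained=pretrained, input_channels=input_channels,
        normalization="minmax" if encoder_name == "tiny" else "imagenet")
    if pretrained:
        state = dict(np.load(weights_path))
        model.load_state_dict(state)
    return learner


def count_parameters(learner: BaseLearner) -> tuple[int, int, int]:
    """Exact ``(trainable, non_trainable, total)`` integer counts."""
    tr, ntr, tot = learner.model.count_params()
    return tr, ntr, tot


def save_checkpoint(learner: BaseLearner, path: str | Path) -> None:
    """Write weights (npz, in parameter order) plus a JSON sidecar
    describing the build (auto-generated layer names are not stable across
    rebuilds, but construction order is)."""
    path = Path(path)
    arrays = {f"p{i:05d}": p.value for i, p in
              enumerate(learner.model.parameters())}
    np.savez(path, **arrays)
    sidecar = {
        "encoder": learner.encoder.name,
        "n_classes": learner.n_classes,
        "input_channels": learner.input_channels,
        "normalization": learner.normalization,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> BaseLearner:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    learner = build_base_learner(sidecar["encoder"], sidecar["n_classes"],
                                 input_channels=sidecar["input_channels"])
    state = np.load(path)
    params = learner.model.parameters()
    if len(state.files) != len(params):
        raise ValueError(f"checkpoint has {len(state.files)} arrays, model "
                         f"expects {len(params)}")
    for i, p in enumerate(params):
        arr = np.asarray(state[f"p{i:05d}"], dtype=np.float32)
        if arr.shape != p.value.shape:
            raise ValueError(f"shape mismatch for parameter {i} ({p.name})")
        p.value = arr.copy()
    return learner
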