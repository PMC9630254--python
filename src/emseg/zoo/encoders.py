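"""Classification-backbone encoders expressed in the emseg.nn graph.

Each builder takes the input node and returns ``(output, skips)`` where
``output`` is the deepest activation (1/32 scale — the U-Net bottleneck once
the decoder is attached) and ``skips`` are the long-skip feature nodes,
ordered deepest-first (1/16, 1/8, 1/4, 1/2[, 1/1]).

The ResNet/SeResNet family uses the pre-activation residual layout (initial
unscaled BN on the raw input, BN-ReLU before each convolution, 1x1
projection shortcuts on the first unit of every stage).  VGG is the plain
stacked 3x3 design with biases.  InceptionV3 and EfficientNet follow the
familiar mixed-block / MBConv designs.  Parameter counts of the resulting
U-Nets reproduce the published totals for these backbones exactly (see
tests), which is what pins down details such as shortcut placement and
which batch norms carry a scale.
"""

from __future__ import annotations

import math

import numpy as np

from .. import nn

__all__ = ["ENCODERS", "EncoderDef"]


def _conv_bn(x, filters, kernel, rng, strides=1, padding="same", act="relu",
             scale=True, name=None):
    x = nn.Conv2D(filters, kernel, strides=strides, padding=padding,
                  use_bias=False, rng=rng, name=name)(x)
    x = nn.BatchNorm(scale=scale)(x)
    return nn.Activation(act)(x)


def _channel_se(x, channels, reduction, rng):
    s = nn.GlobalAvgPool()(x)
    s = nn.Conv2D(channels // reduction, 1, use_bias=True, rng=rng)(s)
    s = nn.Activation("relu")(s)
    s = nn.Conv2D(channels, 1, use_bias=True, rng=rng)(s)
    s = nn.Activation("sigmoid")(s)
    return nn.Multiply()([x, s])


# ---------------------------------------------------------------------------
# ResNet / SeResNet (pre-activation)
# ---------------------------------------------------------------------------

def _resnet(x, rng, repetitions, se=False):
    filters = (64, 128, 256, 512)
    x = nn.BatchNorm(scale=False, name="bn_data")(x)
    x = nn.ZeroPadding2D(3)(x)
    x = nn.Conv2D(64, 7, strides=2, padding="valid", use_bias=False, rng=rng,
                  name="conv0")(x)
    x = nn.BatchNorm(name="bn0")(x)
    x = nn.Activation("relu", name="relu0")(x)
    relu0 = x
    x = nn.ZeroPadding2D(1)(x)
    x = nn.MaxPool2D(3, 2, "valid", name="pooling0")(x)

    stage_skips = []
    for stage, rep in enumerate(repetitions):
        for block in range(rep):
            f = filters[stage]
            strides = 2 if (block == 0 and stage > 0) else 1
            pre = nn.BatchNorm()(x)
            pre = nn.Activation("relu",
                                name=f"stage{stage + 1}_unit{block + 1}_relu1")(pre)
            if block == 0:
                if stage > 0:
                    stage_skips.append(pre)
                shortcut = nn.Conv2D(f, 1, strides=strides, use_bias=False,
                                     rng=rng)(pre)
            else:
                shortcut = x
            y = nn.ZeroPadding2D(1)(pre)
            y = nn.Conv2D(f, 3, strides=strides, padding="valid", use_bias=False,
                          rng=rng)(y)
            y = nn.BatchNorm()(y)
            y = nn.Activation("relu")(y)
            y = nn.ZeroPadding2D(1)(y)
            y = nn.Conv2D(f, 3, padding="valid", use_bias=False, rng=rng)(y)
            if se:
                y = _channel_se(y, f, reduction=16, rng=rng)
            x = nn.Add()([y, shortcut])
    x = nn.BatchNorm(name="bn1")(x)
    x = nn.Activation("relu", name="relu1")(x)
    skips = stage_skips[::-1] + [relu0]  # 1/16, 1/8, 1/4, 1/2
    return x, skips


def resnet18(x, rng):
    return _resnet(x, rng, (2, 2, 2, 2))


def resnet34(x, rng):
    return _resnet(x, rng, (3, 4, 6, 3))


def seresnet34(x, rng):
    return _resnet(x, rng, (3, 4, 6, 3), se=True)


# ---------------------------------------------------------------------------
# VGG
# ---------------------------------------------------------------------------

def _vgg(x, rng, cfg):
    skips = []
    for block, (f, n) in enumerate(cfg, start=1):
        for c in range(1, n + 1):
            x = nn.Conv2D(f, 3, use_bias=True, rng=rng,
                          name=f"block{block}_conv{c}")(x)
            x = nn.Activation("relu")(x)
        skips.append(x)
        x = nn.MaxPool2D(2, 2, name=f"block{block}_pool")(x)
    return x, skips[::-1]  # five skips: 1/16 ... 1/1


def vgg16(x, rng):
    return _vgg(x, rng, [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)])


def vgg19(x, rng):
    return _vgg(x, rng, [(64, 2), (128, 2), (256, 4), (512, 4), (512, 4)])


# ---------------------------------------------------------------------------
# InceptionV3
# ---------------------------------------------------------------------------

def inceptionv3(x, rng):
    def cb(x, f, k, s=1, name=None):
        # Inception batch norms carry no scale (gamma folded into the conv).
        return _conv_bn(x, f, k, rng, strides=s, scale=False, name=name)

    x = cb(x, 32, 3, s=2)
    x = cb(x, 32, 3)
    x = cb(x, 64, 3, name="stem_conv64")
    skip_2 = x                               # 64 ch @ 1/2
    x = nn.MaxPool2D(3, 2, "same")(x)
    x = cb(x, 80, 1)
    x = cb(x, 192, 3, name="stem_conv192")
    skip_4 = x                               # 192 ch @ 1/4
    x = nn.MaxPool2D(3, 2, "same")(x)

    def mixed_a(x, pool_proj):
        b0 = cb(x, 64, 1)
        b1 = cb(cb(x, 48, 1), 64, 5)
        b2 = cb(cb(cb(x, 64, 1), 96, 3), 96, 3)
        b3 = cb(nn.AvgPool2D(3, 1, "same")(x), pool_proj, 1)
        return nn.Concatenate()([b0, b1, b2, b3])

    x = mixed_a(x, 32)                       # mixed0: 256
    x = mixed_a(x, 64)                       # mixed1: 288
    x = mixed_a(x, 64)                       # mixed2: 288
    skip_8 = x                               # 288 ch @ 1/8

    b0 = cb(x, 384, 3, s=2)
    b1 = cb(cb(cb(x, 64, 1), 96, 3), 96, 3, s=2)
    b2 = nn.MaxPool2D(3, 2, "same")(x)
    x = nn.Concatenate()([b0, b1, b2])       # mixed3: 768

    def mixed_b(x, f):
        b0 = cb(x, 192, 1)
        b1 = cb(cb(cb(x, f, 1), f, (1, 7)), 192, (7, 1))
        b2 = cb(cb(cb(cb(cb(x, f, 1), f, (7, 1)), f, (1, 7)), f, (7, 1)),
                192, (1, 7))
        b3 = cb(nn.AvgPool2D(3, 1, "same")(x), 192, 1)
        return nn.Concatenate()([b0, b1, b2, b3])

    x = mixed_b(x, 128)                      # mixed4
    x = mixed_b(x, 160)                      # mixed5
    x = mixed_b(x, 160)                      # mixed6
    x = mixed_b(x, 192)                      # mixed7
    skip_16 = x                              # 768 ch @ 1/16

    b0 = cb(cb(x, 192, 1), 320, 3, s=2)
    b1 = cb(cb(cb(cb(x, 192, 1), 192, (1, 7)), 192, (7, 1)), 192, 3, s=2)
    b2 = nn.MaxPool2D(3, 2, "same")(x)
    x = nn.Concatenate()([b0, b1, b2])       # mixed8: 1280

    def mixed_c(x):
        b0 = cb(x, 320, 1)
        b1 = cb(x, 384, 1)
        b1 = nn.Concatenate()([cb(b1, 384, (1, 3)), cb(b1, 384, (3, 1))])
        b2 = cb(cb(x, 448, 1), 384, 3)
        b2 = nn.Concatenate()([cb(b2, 384, (1, 3)), cb(b2, 384, (3, 1))])
        b3 = cb(nn.AvgPool2D(3, 1, "same")(x), 192, 1)
        return nn.Concatenate()([b0, b1, b2, b3])

    x = mixed_c(x)                           # mixed9
    x = mixed_c(x)                           # mixed10: 2048
    return x, [skip_16, skip_8, skip_4, skip_2]


# ---------------------------------------------------------------------------
# EfficientNet
# ---------------------------------------------------------------------------

_EFFNET_BLOCKS = [
    # kernel, repeats, in, out, expand, stride
    (3, 1, 32, 16, 1, 1),
    (3, 2, 16, 24, 6, 2),
    (5, 2, 24, 40, 6, 2),
    (3, 3, 40, 80, 6, 2),
    (5, 3, 80, 112, 6, 1),
    (5, 4, 112, 192, 6, 2),
    (3, 1, 192, 320, 6, 1),
]


def _round_filters(filters: int, width: float, divisor: int = 8) -> int:
    f = filters * width
    new = max(divisor, int(f + divisor / 2) // divisor * divisor)
    if new < 0.9 * f:
        new += divisor
    return int(new)


def _efficientnet(x, rng, width: float, depth: float):
    x = _conv_bn(x, _round_filters(32, width), 3, rng, strides=2, act="swish")
    skips = {}
    stage_strided = {2: "1/2", 3: "1/4", 4: "1/8", 6: "1/16"}
    for stage, (k, r, cin, cout, e, s) in enumerate(_EFFNET_BLOCKS, start=1):
        cin = _round_filters(cin, width)
        cout = _round_filters(cout, width)
        for rep in range(math.ceil(r * depth)):
            stride = s if rep == 0 else 1
            inp = x
            in_ch = cin if rep == 0 else cout
            expanded = in_ch * e
            if e != 1:
                x = _conv_bn(x, expanded, 1, rng, act="swish",
                             name=f"block{stage}{'abcdefghij'[rep]}_expand")
                if rep == 0 and stage in stage_strided:
                    skips[stage_strided[stage]] = x
            x = nn.DepthwiseConv2D(k, strides=stride, rng=rng)(x)
            x = nn.BatchNorm()(x)
            x = nn.Activation("swish")(x)
            # squeeze-excite, reduction based on the block's input width
            se_ch = max(1, int(in_ch * 0.25))
            se = nn.GlobalAvgPool()(x)
            se = nn.Conv2D(se_ch, 1, use_bias=True, rng=rng)(se)
            se = nn.Activation("swish")(se)
            se = nn.Conv2D(expanded, 1, use_bias=True, rng=rng)(se)
            se = nn.Activation("sigmoid")(se)
            x = nn.Multiply()([x, se])
            x = nn.Conv2D(cout, 1, use_bias=False, rng=rng)(x)
            x = nn.BatchNorm()(x)
            if stride == 1 and in_ch == cout:
                x = nn.Add()([x, inp])
    x = _conv_bn(x, _round_filters(1280, width), 1, rng, act="swish",
                 name="top_conv")
    return x, [skips["1/16"], skips["1/8"], skips["1/4"], skips["1/2"]]


def efficientnetb0(x, rng):
    return _efficientnet(x, rng, width=1.0, depth=1.0)


def efficientnetb4(x, rng):
    return _efficientnet(x, rng, width=1.4, depth=1.8)


# ---------------------------------------------------------------------------
# Tiny encoder for tests and phantom-scale experiments (not pre-trained)
# ---------------------------------------------------------------------------

def tiny(x, rng):
    widths = (8, 16, 24, 32, 48)
    skips = []
    for i, f in enumerate(widths):
        x = _conv_bn(x, f, 3, rng, strides=2, name=f"tiny_stage{i + 1}")
        if i < 4:
            skips.append(x)
    x = _conv_bn(x, 64, 3, rng, name="tiny_deep")
    return x, skips[::-1]


class EncoderDef:
    """Registry entry: how to build an encoder and its ensemble metadata."""

    def __init__(self, name, builder, has_short_skips, in_default_ensemble,
                 pretrained_available, decoder_filters=(256, 128, 64, 32, 16)):
        self.name = name
        self.builder = builder
        self.has_short_skips = has_short_skips
        self.in_default_ensemble = in_default_ensemble
        self.pretrained_available = pretrained_available
        self.decoder_filters = tuple(decoder_filters)


ENCODERS: dict[str, EncoderDef] = {
    "resnet34": EncoderDef("resnet34", resnet34, True, True, True),
    "inceptionv3": EncoderDef("inceptionv3", inceptionv3, False, True, True),
    "vgg19": EncoderDef("vgg19", vgg19, False, True, True),
    "seresnet34": EncoderDef("seresnet34", seresnet34, True, True, True),
    "efficientnetb4": EncoderDef("efficientnetb4", efficientnetb4, True, True, True),
    "resnet18": EncoderDef("resnet18", resnet18, True, False, True),
    "vgg16": EncoderDef("vgg16", vgg16, False, False, True),
    "efficientnetb0": EncoderDef("efficientnetb0", efficientnetb0, True, False, True),
    "tiny": EncoderDef("tiny", tiny, False, False, False,
                       decoder_filters=(32, 24, 16, 12, 8)),
}
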