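"""Grad-CAM closed-form fixtures and saliency contracts."""

import numpy as np
import pytest

from emseg import nn
from emseg.gradcam import class_score, gradcam_map, overlay_heatmap
from emseg.zoo import BaseLearner, EncoderSpec, build_base_learner


def _single_filter_learner():
    """Frozen 1-filter fixture: bottleneck A (1 ch, 2x2), logits = conv1x1(A).

    Y^c = sum_ij w_c * A_ij + Z*b_c, so dY/dA_ij = w_c everywhere, the
    filter weight is w_c, and the map is ReLU(w_c^2 * A) before scaling.
    """
    inp = nn.Input(1)
    pool = nn.MaxPool2D(32, 32)  # 64x64 -> 2x2 "bottleneck"
    bott = pool(inp)
    conv = nn.Conv2D(2, 1, use_bias=True, rng=np.random.default_rng(0),
                     name="head")
    logits = conv(bott)
    probs = nn.Activation("softmax")(logits)
    model = nn.Model(inp, probs)
    conv.w.value = np.array([[[[1.5]]], [[[-0.7]]]], np.float32)
    conv.b.value = np.zeros(2, np.float32)
    spec = EncoderSpec("fixture", False, (), False)
    return BaseLearner(encoder=spec, n_classes=2, model=model, bottleneck=bott,
                       logits=logits, pretrained=False, input_channels=1,
                       normalization="minmax"), conv


class TestClassScore:
    def test_score_and_stack_shapes(self):
        learner, conv = _single_filter_learner()
        img = np.arange(64 * 64, dtype=np.float64).reshape(64, 64)
        y, stack = class_score(learner, img, 0)
        assert stack.activations.shape == (1, 2, 2)
        assert stack.gradients.shape == (1, 2, 2)
        assert stack.Z == 4
        # Y^c = w_c * sum(A)
        assert y == pytest.approx(1.5 * stack.activations.sum(), rel=1e-5)

    def test_gradients_equal_head_weight(self):
        learner, conv = _single_filter_learner()
        img = np.random.default_rng(1).random((64, 64))
        _, stack = class_score(learner, img, 0)
        assert np.allclose(stack.gradients, 1.5, atol=1e-6)
        _, stack = class_score(learner, img, 1)
        assert np.allclose(stack.gradients, -0.7, atol=1e-6)

    def test_doubling_head_weights_doubles_score(self):
        learner, conv = _single_filter_learner()
        img = np.random.default_rng(2).random((64, 64))
        y1, _ = class_score(learner, img, 0)
        conv.w.value = conv.w.value * 2
        conv.b.value = conv.b.value * 2
        y2, _ = class_score(learner, img, 0)
        assert y2 == pytest.approx(2 * y1, rel=1e-5)

    def test_zeroed_head_gives_zero_gradients(self):
        learner, conv = _single_filter_learner()
        conv.w.value = np.zeros_like(conv.w.value)
        conv.b.value = np.array([0.3, -0.1], np.float32)
        img = np.random.default_rng(3).random((64, 64))
        y, stack = class_score(learner, img, 0)
        assert y == pytest.approx(0.3 * 4, rel=1e-5)  # bias-driven constant
        assert np.allclose(stack.gradients, 0.0)

    def test_bottleneck_spatial_area_on_tiny(self, phantom_samples):
        learner = build_base_learner("tiny", 3, seed=0)
        _, stack = class_score(learner, phantom_samples[0].image, 0)
        assert stack.Z == 4  # 64x64 input, five downsamplings -> 2x2

    def test_invalid_class_rejected(self):
        learner, _ = _single_filter_learner()
        with pytest.raises(ValueError):
            class_score(learner, np.zeros((64, 64)), 5)

    def test_unknown_layer_rejected(self):
        learner, _ = _single_filter_learner()
        with pytest.raises(KeyError):
            class_score(learner, np.zeros((64, 64)), 0, layer_name="nope")


class TestGradcamMap:
    def test_closed_form_single_filter(self):
        """Map equals ReLU(w * A) (up to the common min-max scaling)."""
        learner, conv = _single_filter_learner()
        img = np.random.default_rng(4).random((64, 64))
        sal = gradcam_map(learner, img, 0)
        _, stack = class_score(learner, img, 0)
        expected = np.maximum(1.5 * stack.activations[0], 0.0)
        from scipy import ndimage
        expected = ndimage.zoom(expected, 32, order=1, mode="nearest",
                                grid_mode=True)
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(sal.values, expected, atol=1e-6)

    def test_all_negative_sum_gives_zero_map(self):
        learner, conv = _single_filter_learner()
        img = np.random.default_rng(5).random((64, 64))
        sal = gradcam_map(learner, img, 1)  # w_c = -0.7, activations >= 0
        assert np.all(sal.values == 0.0)

    def test_zero_gradients_give_zero_map(self):
        learner, conv = _single_filter_learner()
        conv.w.value = np.zeros_like(conv.w.value)
        sal = gradcam_map(learner, np.random.default_rng(6).random((64, 64)), 0)
        assert np.all(sal.values == 0.0)

    def test_nonnegative_and_normalized_fuzz(self, phantom_samples):
        learner = build_base_learner("tiny", 3, seed=3)
        for i, cid in [(0, 0), (1, 1), (2, 2)]:
            sal = gradcam_map(learner, phantom_samples[i].image, cid)
            assert sal.values.shape == phantom_samples[i].image.shape
            assert sal.values.min() >= 0.0
            assert sal.values.max() <= 1.0 + 1e-6

    def test_invariant_to_input_intensity_rescale(self, phantom_samples):
        """Min-max input normalization absorbs global intensity scaling."""
        learner = build_base_learner("tiny", 3, seed=4)
        img = phantom_samples[0].image.astype(np.float64)
        a = gradcam_map(learner, img, 1).values
        b = gradcam_map(learner, img * 0.5 + 10.0, 1).values
        assert np.allclose(a, b, atol=1e-4)


class TestOverlay:
    def test_alpha_zero_returns_grayscale_image(self, phantom_samples):
        learner = build_base_learner("tiny", 3, seed=0)
        img = phantom_samples[0].image
        sal = gradcam_map(learner, img, 0)
        out = overlay_heatmap(img, sal, alpha=0.0)
        gray = (img - img.min()) / (img.max() - img.min())
        assert out.shape == (*img.shape, 3)
        assert np.abs(out[..., 0] / 255.0 - gray).max() < 0.01

    def test_zero_map_gives_uniform_cold_tint(self, phantom_samples):
        learner, conv = _single_filter_learner()
        conv.w.value = np.zeros_like(conv.w.value)
        img = phantom_samples[0].image
        sal = gradcam_map(learner, img, 0)
        out = overlay_heatmap(img, sal, alpha=1.0)
        # colormap floor: every pixel the same cold (blue-dominant) color
        assert np.all(out == out[0, 0])
        assert out[0, 0, 2] > out[0, 0, 0]

    def test_shape_contract(self, phantom_samples):
        learner = build_base_learner("tiny", 3, seed=0)
        img = phantom_samples[1].image
        sal = gradcam_map(learner, img, 2)
        assert overlay_heatmap(img, sal, 0.5).shape == (*img.shape, 3)
        with pytest.raises(ValueError):
            overlay_heatmap(img[:32], sal, 0.5)
        with pytest.raises(ValueError):
            overlay_heatmap(img, sal, 1.5)
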