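"""Network contracts: layer gradients, shapes, determinism, checkpoints."""

import numpy as np
import pytest

from orgamorph.nn.model import (
    ModelConfig,
    MultiScaleBlock,
    build_model,
    load_model,
    predict_mask,
    save_model,
)
from orgamorph.nn.ops import BatchNorm2d, Conv2d, MaxPool2, ReLU, Sigmoid, UpsampleNearest2


def _fd_check_inputs(layer, x, n_probes=6, eps=1e-6, tol=1e-6):
    """Finite-difference check of d(sum(t*out))/d(x) in float64."""
    rng = np.random.default_rng(0)
    t = rng.random(layer.forward(x, train=True).shape)
    layer.forward(x, train=True)
    dx = layer.backward(t.copy())
    flat = x.reshape(-1)
    for idx in rng.choice(flat.size, n_probes, replace=False):
        old = flat[idx]
        flat[idx] = old + eps
        up = float((layer.forward(x, train=True) * t).sum())
        flat[idx] = old - eps
        dn = float((layer.forward(x, train=True) * t).sum())
        flat[idx] = old
        fd = (up - dn) / (2 * eps)
        assert dx.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=tol)


def _cast_params(layer):
    for p in layer.params():
        p.value = p.value.astype(np.float64)
        p.grad = p.grad.astype(np.float64)
    return layer


class TestLayerGradients:
    def test_conv_3x3(self, rng):
        _fd_check_inputs(_cast_params(Conv2d(2, 3, 3, rng)), rng.random((2, 2, 6, 6)))

    def test_conv_7x7(self, rng):
        _fd_check_inputs(_cast_params(Conv2d(1, 2, 7, rng)), rng.random((1, 1, 9, 9)))

    def test_conv_weight_gradients(self, rng):
        layer = _cast_params(Conv2d(2, 2, 3, rng))
        x = rng.random((2, 2, 5, 5))
        t = rng.random((2, 2, 5, 5))
        layer.forward(x, train=True)
        layer.backward(t.copy())
        eps = 1e-6
        for p in layer.params():
            flat = p.value.reshape(-1)
            for idx in rng.choice(flat.size, min(4, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                up = float((layer.forward(x, train=True) * t).sum())
                flat[idx] = old - eps
                dn = float((layer.forward(x, train=True) * t).sum())
                flat[idx] = old
                fd = (up - dn) / (2 * eps)
                assert p.grad.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_batchnorm(self, rng):
        _fd_check_inputs(_cast_params(BatchNorm2d(3)), rng.random((4, 3, 4, 4)))

    def test_relu(self, rng):
        _fd_check_inputs(ReLU(), rng.random((2, 2, 4, 4)) - 0.5)

    def test_sigmoid(self, rng):
        _fd_check_inputs(Sigmoid(), rng.random((2, 1, 4, 4)) - 0.5, tol=1e-5)

    def test_maxpool(self, rng):
        _fd_check_inputs(MaxPool2(), rng.random((2, 2, 6, 6)))

    def test_upsample(self, rng):
        _fd_check_inputs(UpsampleNearest2(), rng.random((2, 2, 3, 3)))

    def test_multiscale_block(self, rng):
        blk = MultiScaleBlock(2, 4, (3, 7), rng)
        _cast_params(blk.conv_small)
        _cast_params(blk.conv_large)
        _cast_params(blk.bn1)
        _cast_params(blk.fuse)
        _cast_params(blk.bn2)
        _cast_params(blk.proj)
        _fd_check_inputs(blk, rng.random((2, 2, 8, 8)), tol=1e-5)


class TestModelContracts:
    def test_output_shape_matches_input(self):
        model = build_model(ModelConfig(depth=1, base_channels=4, seed=0))
        out = model.forward(np.zeros((1, 1, 64, 64), dtype=np.float32), train=False)
        assert out.shape == (1, 1, 64, 64)

    def test_probabilities_bounded(self, rng):
        model = build_model(ModelConfig(depth=2, base_channels=4, seed=1))
        out = model.forward(rng.random((1, 1, 32, 32)).astype(np.float32), train=False)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_same_seed_identical_weights(self):
        a = build_model(ModelConfig(depth=2, base_channels=4, seed=5))
        b = build_model(ModelConfig(depth=2, base_channels=4, seed=5))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_different_seed_different_weights(self):
        a = build_model(ModelConfig(depth=1, base_channels=4, seed=1))
        b = build_model(ModelConfig(depth=1, base_channels=4, seed=2))
        assert any(
            not np.array_equal(pa.value, pb.value)
            for pa, pb in zip(a.params(), b.params())
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=0)
        with pytest.raises(ValueError):
            ModelConfig(base_channels=0)


class TestPredictMask:
    def test_non_multiple_dims_padded_and_cropped(self, rng):
        model = build_model(ModelConfig(depth=2, base_channels=4, seed=0))
        img = rng.integers(0, 256, size=(70, 90), dtype=np.uint8)
        prob, mask = predict_mask(model, img)
        assert prob.shape == (70, 90) and mask.shape == (70, 90)

    def test_zeroed_head_gives_half_probability_empty_mask(self):
        model = build_model(ModelConfig(depth=1, base_channels=4, seed=0))
        model.head.w.value[...] = 0.0
        model.head.b.value[...] = 0.0
        img = np.random.default_rng(0).integers(0, 256, (32, 32), dtype=np.uint8)
        prob, mask = predict_mask(model, img, threshold=0.5)
        np.testing.assert_allclose(prob, 0.5, atol=1e-6)
        assert mask.foreground_count() == 0  # strict > comparison

    def test_threshold_monotonicity(self, rng):
        model = build_model(ModelConfig(depth=1, base_channels=4, seed=3))
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        _, lo = predict_mask(model, img, threshold=0.3)
        _, hi = predict_mask(model, img, threshold=0.7)
        assert not (hi.pixels & ~lo.pixels).any()

    def test_too_small_image_rejected(self):
        model = build_model(ModelConfig(depth=4, base_channels=4, seed=0))
        with pytest.raises(ValueError):
            predict_mask(model, np.zeros((8, 8), dtype=np.uint8))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(ModelConfig(depth=2, base_channels=4, seed=9))
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        before, _ = predict_mask(model, img)
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        restored = load_model(path)
        after, _ = predict_mask(restored, img)
        np.testing.assert_array_equal(before, after)
        assert restored.config == model.config
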