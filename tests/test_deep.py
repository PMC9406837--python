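"""CNN primitives against brute-force loop oracles; backbone contract."""

import numpy as np
import pytest

from histofusion.deep import (BackboneSpec, avg_pool, conv2d,
                              extract_deep_features, max_pool, register_adapter,
                              relu)
from histofusion.errors import ConfigurationError


def brute_conv2d(x, f, stride, pad):
    """Quadruple-loop cross-correlation oracle."""
    C, H, W = x.shape
    F, _, kh, kw = f.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (W + 2 * pad - kw) // stride + 1
    out = np.zeros((F, oh, ow))
    for ff in range(F):
        for i in range(oh):
            for j in range(ow):
                acc = 0.0
                for c in range(C):
                    for a in range(kh):
                        for b in range(kw):
                            acc += xp[c, i * stride + a, j * stride + b] * f[ff, c, a, b]
                out[ff, i, j] = acc
    return out


def brute_pool(x, k, stride, op):
    C, H, W = x.shape
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    out = np.zeros((C, oh, ow))
    for c in range(C):
        for i in range(oh):
            for j in range(ow):
                win = x[c, i * stride:i * stride + k, j * stride:j * stride + k]
                out[c, i, j] = win.max() if op == "max" else win.mean()
    return out


class TestConv2d:
    def test_ones_sum(self):
        out = conv2d(np.ones((3, 3)), np.ones((2, 2)))
        assert out.shape == (1, 2, 2)
        assert np.allclose(out, 4.0)

    def test_stride_output_shape(self):
        out = conv2d(np.ones((5, 5)), np.ones((3, 3)), stride=2)
        assert out.shape == (1, 2, 2)

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal((2, 6, 6))
        f = rng.standard_normal((3, 2, 3, 3))
        for stride, pad in [(1, 0), (1, 1), (2, 0), (2, 1)]:
            assert np.allclose(conv2d(x, f, stride, pad),
                               brute_conv2d(x, f, stride, pad), atol=1e-9)

    def test_oversized_filter_rejected(self):
        with pytest.raises(ValueError):
            conv2d(np.ones((3, 3)), np.ones((5, 5)))

    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            conv2d(np.ones((4, 4)), np.ones((2, 2)), stride=0)


class TestPooling:
    def test_two_by_two_window(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert max_pool(x, 2).item() == 4.0
        assert avg_pool(x, 2).item() == 2.5

    def test_constant_input(self):
        x = np.full((1, 4, 4), 7.0)
        assert np.allclose(max_pool(x, 2, 2), 7.0)
        assert np.allclose(avg_pool(x, 2, 2), 7.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal((2, 8, 8))
        assert np.allclose(max_pool(x, 2, 2), brute_pool(x, 2, 2, "max"))
        assert np.allclose(avg_pool(x, 3, 1), brute_pool(x, 3, 1, "mean"))

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.ones((2, 2)), 3)


def test_relu():
    assert relu(np.array(-3.0)) == 0.0
    assert relu(np.array(5.0)) == 5.0
    out = relu(np.random.default_rng(0).standard_normal(100))
    assert out.min() >= 0.0


class TestBackbones:
    def test_identical_images_identical_rows(self, random_rgb):
        img = random_rgb(24, 24)
        feats = extract_deep_features([img, img.copy()], BackboneSpec(name="stub"))
        assert np.array_equal(feats[0], feats[1])

    def test_stub_output_width_default_4096(self, random_rgb):
        feats = extract_deep_features([random_rgb(20, 20) for _ in range(3)],
                                      BackboneSpec(name="stub"))
        assert feats.shape == (3, 4096)

    def test_weights_seed_changes_features(self, random_rgb):
        imgs = [random_rgb(16, 16)]
        a = extract_deep_features(imgs, BackboneSpec(name="stub", weights_seed=1))
        b = extract_deep_features(imgs, BackboneSpec(name="stub", weights_seed=2))
        assert not np.allclose(a, b)

    def test_minicnn_contract(self, random_rgb):
        spec = BackboneSpec(name="minicnn", output_dim=64, input_size=(32, 32))
        imgs = [random_rgb(16, 16) for _ in range(2)]
        feats = extract_deep_features(imgs, spec)
        assert feats.shape == (2, 64)
        assert np.array_equal(feats, extract_deep_features(imgs, spec))

    def test_unknown_adapter_raises_configuration_error(self, random_rgb):
        with pytest.raises(ConfigurationError):
            extract_deep_features([random_rgb(8, 8)],
                                  BackboneSpec(name="adapter:not-registered"))

    def test_registered_adapter_is_used_and_checked(self, random_rgb):
        register_adapter("testlinear",
                         lambda imgs, spec: np.ones((len(imgs), spec.output_dim)))
        feats = extract_deep_features([random_rgb(8, 8)],
                                      BackboneSpec(name="adapter:testlinear",
                                                   output_dim=10))
        assert feats.shape == (1, 10)
        register_adapter("badshape", lambda imgs, spec: np.ones((len(imgs), 3)))
        with pytest.raises(ConfigurationError):
            extract_deep_features([random_rgb(8, 8)],
                                  BackboneSpec(name="adapter:badshape", output_dim=10))
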