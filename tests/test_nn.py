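"""Numerical verification of the numpy network engine.

Every backward pass is checked against central finite differences in
float64 on small geometries; the optimizer and loss are checked against
closed forms.
"""

import numpy as np
import pytest
from scipy.special import log_softmax as scipy_log_softmax

from scratchdet.nn import (
    Adam,
    BatchNorm2d,
    BiGRU,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Sequential,
    softmax_cross_entropy,
)
from scratchdet.nn.functional import resize_bilinear_batch


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def _check_layer(layer, x, train=True):
    """Finite-difference check of input and parameter gradients."""
    layer.astype(np.float64)
    layer.train() if train else layer.eval()
    rng = np.random.default_rng(0)
    w_out = None

    def loss():
        y = layer.forward(x)
        nonlocal w_out
        if w_out is None:
            w_out = rng.normal(size=y.shape)
        return float((y * w_out).sum())

    base = loss()
    layer.zero_grad()
    dx = layer.backward(w_out)
    assert np.allclose(dx, _num_grad(loss, x), atol=1e-5), "input gradient"
    for k, p in enumerate(layer.parameters()):
        num = _num_grad(loss, p.value)
        assert np.allclose(p.grad, num, atol=1e-5), f"parameter {k} gradient"


class TestLayerGradients:
    def test_conv2d(self, rng):
        layer = Conv2d(2, 3, 3, stride=2, pad=1, bias=True,
                       rng=np.random.default_rng(1))
        _check_layer(layer, rng.normal(size=(2, 2, 7, 7)))

    def test_batchnorm_train_mode(self, rng):
        _check_layer(BatchNorm2d(3), rng.normal(size=(4, 3, 3, 3)))

    def test_batchnorm_eval_mode(self, rng):
        layer = BatchNorm2d(3)
        layer.running_mean = rng.normal(size=3)
        layer.running_var = rng.random(3) + 0.5
        _check_layer(layer, rng.normal(size=(2, 3, 3, 3)), train=False)

    def test_maxpool(self, rng):
        # distinct values so the argmax is stable under the fd perturbation
        x = rng.permutation(np.arange(2 * 2 * 6 * 6, dtype=np.float64))
        _check_layer(MaxPool2d(3, 2, pad=1), x.reshape(2, 2, 6, 6))

    def test_linear_and_pool_stack(self, rng):
        layer = Sequential(GlobalAvgPool(),
                           Linear(3, 4, rng=np.random.default_rng(2)))
        _check_layer(layer, rng.normal(size=(2, 3, 4, 4)))

    def test_bidirectional_two_layer_gru(self, rng):
        layer = BiGRU(3, 4, 2, np.random.default_rng(3))
        _check_layer(layer, rng.normal(size=(2, 5, 3)))


class TestFullModelGradient:
    def test_crnn_input_and_parameter_gradients(self, rng):
        from scratchdet.model import CRNNConfig, CRNNModel

        cfg = CRNNConfig(input_size=(16, 16), n=3, cnn_variant="tiny",
                         cnn_embedding=6, gru_layers=2, gru_hidden=5,
                         fc_hidden=7, fc_dropout=0.0,
                         feature_fusion="concat_cnn_mean")
        model = CRNNModel(cfg, seed=1).astype(np.float64)
        model.train()
        x = rng.normal(0.5, 0.2, size=(2, 3, 16, 16))
        y = np.array([0, 1])

        def loss():
            return softmax_cross_entropy(model.forward(x), y)[0]

        _, dlogits = softmax_cross_entropy(model.forward(x), y)
        model.zero_grad()
        dx = model.backward(dlogits)
        # spot-check input grad and a conv + GRU + head parameter each
        num_dx = np.zeros(4)
        ana_dx = np.zeros(4)
        coords = [(0, 0, 3, 4), (1, 2, 10, 11), (0, 1, 0, 0), (1, 0, 15, 15)]
        for k, c in enumerate(coords):
            eps = 1e-6
            orig = x[c]
            x[c] = orig + eps
            fp = loss()
            x[c] = orig - eps
            fm = loss()
            x[c] = orig
            num_dx[k] = (fp - fm) / (2 * eps)
            ana_dx[k] = dx[c]
        assert np.allclose(num_dx, ana_dx, atol=1e-6)
        params = model.parameters()
        for p in (params[0], params[len(params) // 2], params[-1]):
            flat = p.value.ravel()
            j = flat.size // 2
            eps = 1e-6
            orig = flat[j]
            flat[j] = orig + eps
            fp = loss()
            flat[j] = orig - eps
            fm = loss()
            flat[j] = orig
            assert p.grad.ravel()[j] == pytest.approx((fp - fm) / (2 * eps),
                                                      abs=1e-5)


class TestLossAndOptim:
    def test_cross_entropy_matches_scipy_log_softmax(self, rng):
        logits = rng.normal(size=(8, 2))
        labels = rng.integers(0, 2, size=8)
        loss, _ = softmax_cross_entropy(logits, labels)
        ref = -scipy_log_softmax(logits, axis=1)[np.arange(8), labels].mean()
        assert loss == pytest.approx(ref, rel=1e-12)

    def test_adam_first_step_matches_closed_form(self):
        from scratchdet.nn.layers import Parameter

        p = Parameter(np.array([1.0, -2.0]))
        p.grad[...] = np.array([0.5, -0.25])
        opt = Adam([p], lr=0.01)
        opt.step()
        # with bias correction the first step is -lr * sign(g) (eps-limited)
        assert np.allclose(p.value, [1.0 - 0.01, -2.0 + 0.01], atol=1e-6)

    def test_dropout_scales_and_masks(self, rng):
        d = Dropout(0.5, rng=np.random.default_rng(0))
        x = np.ones((100, 100))
        y = d.forward(x)
        assert set(np.unique(y)) <= {0.0, 2.0}
        d.eval()
        assert np.array_equal(d.forward(x), x)


class TestResize:
    def test_matches_skimage_bilinear(self, rng):
        from skimage.transform import resize as sk_resize

        img = rng.random((1, 40, 40))
        mine = resize_bilinear_batch(img, 25, 25)[0]
        ref = sk_resize(img[0], (25, 25), order=1, anti_aliasing=False)
        assert np.allclose(mine, ref, atol=5e-2)
        assert abs(mine.mean() - ref.mean()) < 5e-3

    def test_identity_when_size_unchanged(self, rng):
        img = rng.random((2, 8, 8))
        assert np.array_equal(resize_bilinear_batch(img, 8, 8), img)
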