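import numpy as np
import pytest

from watercore.nn.layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    QuadConv1d,
    ReLU,
    cross_entropy,
    quad_conv1d,
    same_padding,
    softmax,
)


def naive_quad_conv(x, params, kernel, stride):
    """Triple-loop reference for the quadratic convolution ('same' padding)."""
    n, cin, L = x.shape
    left, right, lo = same_padding(L, kernel, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
    out_ch = params["wr"].shape[0]
    out = np.zeros((n, out_ch, lo))
    for b in range(n):
        for o in range(out_ch):
            wr = params["wr"][o]
            wg = params["wg"][o]
            wb = params["wb"][o]
            for t in range(lo):
                w = xp[b, :, t * stride : t * stride + kernel].reshape(-1)
                u = w @ wr + params["br"][o]
                v = w @ wg + params["bg"][o]
                q = (w * w) @ wb + params["c"][o]
                out[b, o, t] = u * v + q
    return out


def random_quad_params(rng, cin, cout, kernel):
    fan = cin * kernel
    return {
        "wr": rng.normal(size=(cout, fan)),
        "br": rng.normal(size=cout),
        "wg": rng.normal(size=(cout, fan)),
        "bg": rng.normal(size=cout),
        "wb": rng.normal(size=(cout, fan)),
        "c": rng.normal(size=cout),
    }


class TestQuadConvOracle:
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_triple_loop(self, trial):
        rng = np.random.default_rng(200 + trial)
        cin = int(rng.integers(1, 4))
        cout = int(rng.integers(1, 4))
        kernel = int(rng.integers(1, 8))
        stride = int(rng.integers(1, 4))
        L = int(rng.integers(kernel, 51))
        x = rng.normal(size=(2, cin, L))
        params = random_quad_params(rng, cin, cout, kernel)
        fast = quad_conv1d(x, params, kernel, stride)
        slow = naive_quad_conv(x, params, kernel, stride)
        np.testing.assert_allclose(fast, slow, rtol=1e-6, atol=1e-9)

    def test_reduces_to_linear(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(3, 2, 30))
        params = random_quad_params(rng, 2, 4, 5)
        params["wg"][:] = 0.0
        params["bg"][:] = 1.0
        params["wb"][:] = 0.0
        params["c"][:] = 0.0
        out = quad_conv1d(x, params, 5, 2)
        # linear reference via the Conv1d layer sharing w_r
        lin = Conv1d(2, 4, 5, 2, np.random.default_rng(0))
        lin.params["w"] = params["wr"]
        lin.params["b"] = params["br"]
        np.testing.assert_allclose(out, lin.forward(x), rtol=0, atol=1e-12)

    def test_hand_window(self):
        # window [1,2,3]: (6*1+0)*(0+2) + 1^2*1 + 1 = 14 at the centred position
        params = {
            "wr": np.array([[1.0, 1.0, 1.0]]),
            "br": np.array([0.0]),
            "wg": np.array([[0.0, 0.0, 0.0]]),
            "bg": np.array([2.0]),
            "wb": np.array([[1.0, 0.0, 0.0]]),
            "c": np.array([1.0]),
        }
        x = np.array([[[1.0, 2.0, 3.0]]])
        out = quad_conv1d(x, params, 3, 1)
        assert out.shape == (1, 1, 3)
        assert out[0, 0, 1] == pytest.approx(14.0)

    def test_all_zero_weights_constant(self):
        rng = np.random.default_rng(8)
        params = {
            "wr": np.zeros((2, 6)), "br": np.zeros(2),
            "wg": np.zeros((2, 6)), "bg": np.zeros(2),
            "wb": np.zeros((2, 6)), "c": np.full(2, 5.0),
        }
        out = quad_conv1d(rng.normal(size=(2, 2, 20)), params, 3, 1)
        np.testing.assert_allclose(out, 5.0)

    def test_nonfinite_weights_rejected(self):
        params = random_quad_params(np.random.default_rng(9), 1, 1, 3)
        params["wb"][0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            quad_conv1d(np.zeros((1, 1, 10)), params, 3, 1)

    def test_shape_mismatch_rejected(self):
        params = random_quad_params(np.random.default_rng(10), 2, 1, 3)
        with pytest.raises(ValueError, match="fan-in"):
            quad_conv1d(np.zeros((1, 1, 10)), params, 3, 1)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        hi = f()
        x[i] = old - eps
        lo = f()
        x[i] = old
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


class TestGradients:
    """Finite-difference checks of every backward pass."""

    def _check(self, layer, x, params_to_check=True, seed=0):
        rng = np.random.default_rng(seed)
        out = layer.forward(x, training=True)
        R = rng.normal(size=out.shape)

        def loss():
            return float((layer.forward(x, training=True) * R).sum())

        layer.forward(x, training=True)
        dx = layer.backward(R)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), rtol=1e-4, atol=1e-6)
        if params_to_check:
            for key in layer.params:
                got = layer.grads[key]
                want = numeric_grad(loss, layer.params[key])
                np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-6,
                                           err_msg=f"param {key}")

    def test_conv1d(self):
        rng = np.random.default_rng(1)
        self._check(Conv1d(2, 3, 4, 2, rng), rng.normal(size=(2, 2, 12)))

    def test_quadconv1d(self):
        rng = np.random.default_rng(2)
        layer = QuadConv1d(2, 3, 4, 2, rng)
        # move off the linear initialization so all branches are exercised
        for key in ("wg", "wb"):
            layer.params[key] = rng.normal(size=layer.params[key].shape) * 0.3
        layer.params["c"] = rng.normal(size=3)
        self._check(layer, rng.normal(size=(2, 2, 12)))

    def test_batchnorm(self):
        rng = np.random.default_rng(3)
        layer = BatchNorm1d(3)
        layer.params["gamma"] = rng.normal(size=3)
        layer.params["beta"] = rng.normal(size=3)
        self._check(layer, rng.normal(size=(4, 3, 6)))

    def test_dense(self):
        rng = np.random.default_rng(4)
        self._check(Dense(5, 3, rng), rng.normal(size=(4, 5)))

    def test_relu_maxpool_flatten(self):
        rng = np.random.default_rng(5)
        self._check(ReLU(), rng.normal(size=(3, 2, 8)) + 0.05, params_to_check=False)
        self._check(MaxPool1d(2), rng.normal(size=(3, 2, 8)), params_to_check=False)
        self._check(Flatten(), rng.normal(size=(3, 2, 8)), params_to_check=False)


class TestAuxLayers:
    def test_maxpool_values(self):
        x = np.array([[[1.0, 3.0, 2.0, 0.0, -1.0, 5.0]]])
        out = MaxPool1d(2).forward(x, training=False)
        np.testing.assert_array_equal(out, [[[3.0, 2.0, 5.0]]])

    def test_maxpool_indivisible(self):
        with pytest.raises(ValueError, match="divisible"):
            MaxPool1d(2).forward(np.zeros((1, 1, 5)))

    def test_batchnorm_train_normalizes(self):
        rng = np.random.default_rng(6)
        x = rng.normal(3.0, 2.0, size=(8, 2, 50))
        out = BatchNorm1d(2).forward(x, training=True)
        np.testing.assert_allclose(out.mean(axis=(0, 2)), 0.0, atol=1e-7)
        np.testing.assert_allclose(out.std(axis=(0, 2)), 1.0, atol=1e-3)

    def test_batchnorm_eval_uses_running_stats(self):
        layer = BatchNorm1d(1)
        x = np.random.default_rng(7).normal(5.0, 1.0, size=(16, 1, 10))
        for _ in range(200):
            layer.forward(x, training=True)
        out = layer.forward(x, training=False)
        assert abs(out.mean()) < 0.05

    def test_dropout_eval_identity(self):
        layer = Dropout(0.5, np.random.default_rng(8))
        x = np.random.default_rng(9).normal(size=(5, 10))
        np.testing.assert_array_equal(layer.forward(x, training=False), x)

    def test_dropout_train_scales(self):
        layer = Dropout(0.4, np.random.default_rng(10))
        x = np.ones((200, 100))
        out = layer.forward(x, training=True)
        kept = out[out > 0]
        np.testing.assert_allclose(kept, 1.0 / 0.6, rtol=1e-12)
        assert abs((out > 0).mean() - 0.6) < 0.02

    def test_softmax_cross_entropy(self):
        logits = np.array([[2.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        loss, grad = cross_entropy(logits, np.array([0, 2]))
        expected = -(np.log(p[0, 0]) + np.log(p[1, 2])) / 2
        assert loss == pytest.approx(expected)
        np.testing.assert_allclose(grad.sum(axis=1), 0.0, atol=1e-12)
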