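"""NumPy runtime: op gradients vs finite differences, analytic-count equality,
forward shapes and finiteness."""

import numpy as np
import pytest

from bloomdet.architecture import build_architecture, count_parameters
from bloomdet.architecture.params import head_shapes
from bloomdet.runtime import build_runtime_model
from bloomdet.runtime import ops


def numgrad(f, x, h=1e-4):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + h
        fp = f()
        x[idx] = orig - h
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * h)
    return g


class TestOpGradients:
    """Every backward pass agrees with central finite differences."""

    def test_conv2d(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 6, 6))
        w = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        dy = rng.normal(size=(2, 4, 6, 6))

        def loss():
            y, _ = ops.conv2d_forward(x, w, b, stride=1)
            return float((y * dy).sum())

        y, cache = ops.conv2d_forward(x, w, b, stride=1)
        dx, dw, db = ops.conv2d_backward(dy, w, cache, True)
        assert np.allclose(dx, numgrad(loss, x), atol=1e-5)
        assert np.allclose(dw, numgrad(loss, w), atol=1e-5)
        assert np.allclose(db, numgrad(loss, b), atol=1e-5)

    def test_conv2d_stride2(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 2, 8, 8))
        w = rng.normal(size=(3, 2, 3, 3))
        dy = rng.normal(size=(1, 3, 4, 4))

        def loss():
            y, _ = ops.conv2d_forward(x, w, None, stride=2)
            return float((y * dy).sum())

        _, cache = ops.conv2d_forward(x, w, None, stride=2)
        dx, dw, _ = ops.conv2d_backward(dy, w, cache, False)
        assert np.allclose(dx, numgrad(loss, x), atol=1e-5)
        assert np.allclose(dw, numgrad(loss, w), atol=1e-5)

    def test_depthwise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 4, 6, 6))
        w = rng.normal(size=(4, 3, 3))
        dy = rng.normal(size=(2, 4, 6, 6))

        def loss():
            y, _ = ops.depthwise_forward(x, w, None)
            return float((y * dy).sum())

        _, cache = ops.depthwise_forward(x, w, None)
        dx, dw, _ = ops.depthwise_backward(dy, w, cache, False)
        assert np.allclose(dx, numgrad(loss, x), atol=1e-5)
        assert np.allclose(dw, numgrad(loss, w), atol=1e-5)

    def test_batchnorm(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 2, 4, 4))
        gamma = rng.normal(size=2) + 1
        beta = rng.normal(size=2)
        dy = rng.normal(size=(3, 2, 4, 4))

        def loss():
            running = [np.zeros(2), np.ones(2)]
            y, _ = ops.batchnorm_forward(x, gamma, beta, running, train=True)
            return float((y * dy).sum())

        running = [np.zeros(2), np.ones(2)]
        _, cache = ops.batchnorm_forward(x, gamma, beta, running, train=True)
        dx, dgamma, dbeta = ops.batchnorm_backward(dy, cache)
        assert np.allclose(dx, numgrad(loss, x), atol=1e-4)
        assert np.allclose(dgamma, numgrad(loss, gamma), atol=1e-4)
        assert np.allclose(dbeta, numgrad(loss, beta), atol=1e-4)

    @pytest.mark.parametrize("kind", ["leaky_relu", "relu", "relu6", "mish",
                                      "h_swish", "sigmoid"])
    def test_activations(self, kind):
        rng = np.random.default_rng(4)
        # avoid kink points for clean finite differences
        x = rng.normal(size=200) * 2
        x = x[np.all(np.abs(x[None, :] - np.array([[0.0], [-3.0], [3.0], [6.0]])) > 1e-2,
                     axis=0)]
        dy = rng.normal(size=x.shape)

        def loss():
            y, _ = ops.activation_forward(x, kind)
            return float((y * dy).sum())

        _, cache = ops.activation_forward(x, kind)
        dx = ops.activation_backward(dy, cache, kind)
        assert np.allclose(dx, numgrad(loss, x), atol=1e-4)

    def test_maxpool_2x2(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 2, 6, 6))
        dy = rng.normal(size=(1, 2, 3, 3))
        _, cache = ops.maxpool_forward(x, 2, 2)
        dx = ops.maxpool_backward(dy, cache)

        def loss():
            y, _ = ops.maxpool_forward(x, 2, 2)
            return float((y * dy).sum())

        assert np.allclose(dx, numgrad(loss, x), atol=1e-5)

    def test_upsample(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 2, 3, 3))
        dy = rng.normal(size=(1, 2, 6, 6))
        y, cache = ops.upsample_forward(x)
        assert y.shape == (1, 2, 6, 6)
        dx = ops.upsample_backward(dy, cache)

        def loss():
            y, _ = ops.upsample_forward(x)
            return float((y * dy).sum())

        assert np.allclose(dx, numgrad(loss, x), atol=1e-5)

    def test_spp_pool_matches_naive(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 1, 7, 7))
        y, _ = ops.maxpool_forward(x, 5, 1)
        assert y.shape == x.shape
        # naive check at a few positions
        for (i, j) in [(0, 0), (3, 3), (6, 6)]:
            lo_i, hi_i = max(0, i - 2), min(7, i + 3)
            lo_j, hi_j = max(0, j - 2), min(7, j + 3)
            assert y[0, 0, i, j] == x[0, 0, lo_i:hi_i, lo_j:hi_j].max()


class TestRuntimeModel:
    @pytest.mark.parametrize("variant,nc", [
        ("yolov4", 2), ("yolov4_dw", 2), ("yolov4_tiny", 20),
        ("yolov4_tiny_dw", 2), ("improved", 2),
    ])
    def test_param_equality_with_analytic_ledger(self, variant, nc):
        g = build_architecture(variant, num_classes=nc)
        m = build_runtime_model(g)
        report = count_parameters(g)
        assert m.parameter_count() == report.total
        assert m.parameter_count_by_section() == report.by_section

    def test_tiny_forward_shapes_and_finite(self):
        g = build_architecture("yolov4_tiny_dw", num_classes=2, input_size=160)
        m = build_runtime_model(g)
        heads = m.forward(np.zeros((1, 3, 160, 160), dtype=np.float32))
        assert [h.shape for h in heads] == [(1, 10, 10, 21), (1, 5, 5, 21)]
        assert all(np.isfinite(h).all() for h in heads)

    def test_improved_forward_shapes_at_608(self):
        g = build_architecture("improved", num_classes=2, input_size=608)
        m = build_runtime_model(g)
        heads = m.forward(np.zeros((1, 3, 608, 608), dtype=np.float32))
        assert [h.shape for h in heads] == [
            (1, 76, 76, 21), (1, 38, 38, 21), (1, 19, 19, 21)]
        assert all(np.isfinite(h).all() for h in heads)

    def test_yolov4_predicted_head_shapes(self):
        # stride arithmetic on the declarative graph (the runtime pass of the
        # 64M-parameter model at 608 px is exercised implicitly by the
        # parameter-equality check above)
        g = build_architecture("yolov4", num_classes=2, input_size=608)
        assert head_shapes(g) == [(76, 76, 21), (38, 38, 21), (19, 19, 21)]

    def test_state_dict_round_trip(self):
        g = build_architecture("yolov4_tiny_dw", num_classes=2, input_size=96)
        m1 = build_runtime_model(g, seed=1)
        m2 = build_runtime_model(g, seed=2)
        x = np.random.default_rng(0).normal(size=(1, 3, 96, 96)).astype(np.float32)
        m2.load_state_dict(m1.state_dict())
        a = m1.forward(x)
        b = m2.forward(x)
        for ha, hb in zip(a, b):
            assert np.array_equal(ha, hb)

    def test_model_gradient_matches_finite_difference(self):
        """End-to-end gradient through a real graph, in float64.

        The step must be tiny (1e-6): the network is piecewise linear in its
        leaky-ReLU/max-pool kinks and larger steps cross enough kinks to
        bias a finite difference — hence the float64 cast.
        """
        g = build_architecture("yolov4_tiny_dw", num_classes=2, input_size=64)
        m = build_runtime_model(g, seed=0)
        for p in m.params.values():
            for k in p:
                p[k] = p[k].astype(np.float64)
        for b in m.buffers.values():
            for i in range(2):
                b[i] = b[i].astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 3, 64, 64))

        def loss():
            heads = m.forward(x, train=True)
            return float(sum(h.sum() for h in heads))

        heads = m.forward(x, train=True)
        pgrads = m.backward([np.ones_like(h) for h in heads])
        # exact identity: with unit upstream gradient, a predictor's bias
        # gradient is its head's spatial cell count
        predictors = [n.name for n in g.nodes if n.role == "predictor"]
        cell_counts = sorted(int(h.shape[1] * h.shape[2]) for h in heads)
        got = sorted(float(pgrads[p]["b"][0]) for p in predictors)
        assert got == [float(c) for c in cell_counts]
        # finite-difference check of an early backbone weight through the
        # whole depth (train-mode batch norm included)
        first_conv = next(n.name for n in g.nodes if n.kind == "conv")
        arr = m.params[first_conv]["w"]
        idx = (0, 0, 1, 1)
        garr = pgrads[first_conv]["w"][idx]
        orig = arr[idx]
        h = 1e-6
        arr[idx] = orig + h
        fp = loss()
        arr[idx] = orig - h
        fm = loss()
        arr[idx] = orig
        num = (fp - fm) / (2 * h)
        assert garr == pytest.approx(num, rel=1e-4, abs=1e-6)
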