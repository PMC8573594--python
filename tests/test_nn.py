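"""Finite-difference checks of the autodiff engine."""

import numpy as np
import pytest

from wmhda import nn
from wmhda.nn.tensor import Tensor, _interp_matrix


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of scalar f wrt array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_grad(build, arrays, tol=1e-6):
    """build() -> scalar Tensor from the given float64 leaf tensors."""
    out = build()
    out.backward()
    for leaf in arrays:
        analytic = leaf.grad.copy()
        leaf.grad = None
        numeric = numeric_grad(lambda: build().item(), leaf.data)
        np.testing.assert_allclose(analytic, numeric, rtol=tol, atol=tol)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestElementwise:
    def test_arithmetic_chain(self, rng):
        a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((3, 4)) + 2.0, requires_grad=True)
        check_grad(lambda: ((a * b + a - b / 2.0) ** 2).sum(), [a, b], tol=1e-5)

    def test_log_exp_relu(self, rng):
        a = Tensor(rng.standard_normal((5,)), requires_grad=True)
        check_grad(lambda: ((a.exp() + 1.1).log().relu()).sum(), [a], tol=1e-5)

    def test_matmul(self, rng):
        a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((4, 2)), requires_grad=True)
        check_grad(lambda: (a @ b).sum(), [a, b], tol=1e-6)

    def test_broadcast_add(self, rng):
        a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((4,)), requires_grad=True)
        check_grad(lambda: ((a + b) ** 2).mean(), [a, b], tol=1e-5)

    def test_diamond_graph_accumulates(self, rng):
        a = Tensor(np.array([2.0]), requires_grad=True)
        out = a * a + a
        out.backward(np.array([1.0]))
        np.testing.assert_allclose(a.grad, [5.0])


class TestConvPool:
    def test_conv2d_grads(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 5, 6)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 3, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(rng.standard_normal(4), requires_grad=True)
        check_grad(lambda: (nn.conv2d(x, w, b, padding=1) ** 2).sum(), [x, w, b], tol=2e-5)

    def test_conv1x1_grads(self, rng):
        x = Tensor(rng.standard_normal((2, 4, 4, 4)), requires_grad=True)
        w = Tensor(rng.standard_normal((2, 4, 1, 1)), requires_grad=True)
        check_grad(lambda: (nn.conv2d(x, w, None, padding=0) ** 2).sum(), [x, w], tol=2e-5)

    def test_conv_matches_scipy(self, rng):
        from scipy.signal import correlate2d

        x = rng.standard_normal((1, 2, 7, 8))
        w = rng.standard_normal((3, 2, 3, 3))
        out = nn.conv2d(Tensor(x), Tensor(w), None, padding=1).numpy()
        for o in range(3):
            ref = sum(correlate2d(x[0, c], w[o, c], mode="same") for c in range(2))
            np.testing.assert_allclose(out[0, o], ref, atol=1e-10)

    def test_maxpool_grads(self, rng):
        x = Tensor(rng.standard_normal((2, 2, 6, 6)), requires_grad=True)
        check_grad(lambda: (nn.maxpool2d(x, 2) ** 2).sum(), [x], tol=1e-5)

    def test_maxpool_floors_odd_dims(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 5, 7)))
        assert nn.maxpool2d(x, 2).shape == (1, 1, 2, 3)


class TestResizeNormSoftmax:
    def test_interp_matrix_rows_sum_to_one(self):
        for n_in, n_out in [(5, 10), (10, 5), (1, 4), (7, 7)]:
            m = _interp_matrix(n_in, n_out)
            np.testing.assert_allclose(m.sum(axis=1), 1.0)

    def test_resize_identity(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 6, 7)))
        np.testing.assert_allclose(nn.resize_bilinear(x, (6, 7)).numpy(), x.numpy())

    def test_resize_grads(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 4, 6)), requires_grad=True)
        check_grad(lambda: (nn.resize_bilinear(x, (7, 3)) ** 2).sum(), [x], tol=1e-5)

    def test_batchnorm_train_grads(self, rng):
        x = Tensor(rng.standard_normal((4, 3, 5, 5)), requires_grad=True)
        g = Tensor(rng.standard_normal(3) + 1.0, requires_grad=True)
        b = Tensor(rng.standard_normal(3), requires_grad=True)

        def build():
            rm = np.zeros(3)
            rv = np.ones(3)
            return (nn.tensor.batch_norm(x, g, b, rm, rv, training=True) ** 2).sum()

        check_grad(build, [x, g, b], tol=2e-4)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm2d(2, dtype=np.float64)
        bn.running_mean[:] = [1.0, -1.0]
        bn.running_var[:] = [4.0, 0.25]
        bn.eval()
        x = Tensor(rng.standard_normal((2, 2, 3, 3)))
        out = bn(x).numpy()
        expect = (x.numpy() - np.array([1.0, -1.0]).reshape(1, 2, 1, 1)) / np.sqrt(
            np.array([4.0, 0.25]).reshape(1, 2, 1, 1) + bn.eps
        )
        np.testing.assert_allclose(out, expect, rtol=1e-6)

    def test_softmax_rows_sum_to_one_and_grads(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 4, 4)), requires_grad=True)
        p = nn.softmax(x, axis=1)
        np.testing.assert_allclose(p.numpy().sum(axis=1), 1.0, atol=1e-12)
        check_grad(lambda: ((nn.softmax(x, axis=1) + 0.1).log()).sum(), [x], tol=1e-5)

    def test_gather_channel_grads(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 4, 4)), requires_grad=True)
        idx = rng.integers(0, 3, size=(2, 4, 4))
        check_grad(lambda: (nn.gather_channel(x, idx) ** 2).sum(), [x], tol=1e-5)


class TestGradReverse:
    """Acceptance criterion: forward identity, backward -lambda scaling (1e-6)."""

    def test_forward_identity(self, rng):
        x = Tensor(rng.standard_normal((3, 5)))
        np.testing.assert_array_equal(nn.grad_reverse(x, 1.0).numpy(), x.numpy())

    def test_backward_sign_flip(self):
        x = Tensor(np.array([2.0, -4.0]), requires_grad=True)
        out = nn.grad_reverse(x, 1.0).sum()
        out.backward()
        np.testing.assert_allclose(x.grad, [-1.0, -1.0])

    def test_backward_scaling(self):
        x = Tensor(np.array([1.0, 1.0]), requires_grad=True)
        (nn.grad_reverse(x, 0.5) * Tensor(np.array([2.0, -4.0]))).sum().backward()
        np.testing.assert_allclose(x.grad, [-1.0, 2.0])

    def test_finite_difference_through_network(self, rng):
        # -lambda * d(loss)/dx verified numerically through a nonlinear map
        lam = 0.7
        w = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
        x = Tensor(rng.standard_normal((2, 4)), requires_grad=True)

        def plain():
            return ((x @ w).relu() ** 2).sum()

        def reversed_():
            return ((nn.grad_reverse(x, lam) @ w).relu() ** 2).sum()

        reversed_().backward()
        analytic = x.grad.copy()
        numeric_plain = numeric_grad(lambda: plain().item(), x.data)
        np.testing.assert_allclose(analytic, -lam * numeric_plain, rtol=1e-6, atol=1e-6)


class TestModulesOptim:
    def test_state_dict_roundtrip(self):
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(2)
        a = nn.Sequential(nn.Conv2d(2, 4, 3, rng=rng1), nn.BatchNorm2d(4), nn.ReLU())
        b = nn.Sequential(nn.Conv2d(2, 4, 3, rng=rng2), nn.BatchNorm2d(4), nn.ReLU())
        b.load_state_dict(a.state_dict())
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_adam_reduces_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1, eps=1e-4)
        for _ in range(300):
            opt.zero_grad()
            loss = (Tensor(p.data, requires_grad=True) ** 2).sum()
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 0.05

    def test_sgd_momentum_matches_reference(self):
        p = nn.Parameter(np.array([1.0]))
        opt = nn.SGD([p], lr=0.1, momentum=0.9)
        buf, x = 0.0, 1.0
        for _ in range(5):
            g = 2 * p.data[0]
            p.grad = np.array([g])
            opt.step()
            buf = 0.9 * buf + 2 * x
            x = x - 0.1 * buf
            np.testing.assert_allclose(p.data[0], x, rtol=1e-12)

    def test_dropout_eval_is_identity(self):
        d = nn.Dropout(0.5, rng=np.random.default_rng(0))
        d.eval()
        x = Tensor(np.ones((4, 4)))
        np.testing.assert_array_equal(d(x).numpy(), x.numpy())

    def test_dropout_train_scales(self):
        d = nn.Dropout(0.5, rng=np.random.default_rng(0))
        x = Tensor(np.ones((100, 100)))
        out = d(x).numpy()
        assert set(np.unique(out)) <= {0.0, 2.0}
        assert abs(out.mean() - 1.0) < 0.05
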