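"""Autograd engine: every operation checked against central finite differences."""

import numpy as np
import pytest

from condyseg.nn import autograd as ag
from condyseg.nn.layers import BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module
from condyseg.nn.optim import Adam


def numerical_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f with respect to array x."""
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


def check_grads(build_loss, tensors, tol=1e-7):
    """build_loss() -> scalar Tensor; compare autograd to numerical for each input."""
    loss = build_loss()
    loss.backward()
    for t in tensors:
        num = numerical_grad(lambda: build_loss().data.item(), t.data)
        err = np.max(np.abs(t.grad - num)) / max(1.0, np.max(np.abs(num)))
        assert err < tol, f"gradient mismatch {err:.3e}"


def scalar_sum(t):
    """Reduce a tensor to a scalar with known weights so gradients are generic."""
    rng = np.random.default_rng(99)
    w = ag.Tensor(rng.normal(size=t.shape))
    return ag.reshape(ag.mul(t, w), (1, t.data.size)) @ ag.Tensor(
        np.ones((t.data.size, 1))
    )


# make matmul available via @
ag.Tensor.__matmul__ = lambda self, other: ag.matmul(self, other)


def rand_tensor(rng, *shape):
    return ag.Tensor(rng.normal(size=shape), requires_grad=True)


class TestElementwiseOps:
    def test_add_mul_broadcast(self):
        rng = np.random.default_rng(0)
        a = rand_tensor(rng, 2, 3, 4, 4)
        b = rand_tensor(rng, 1, 3, 1, 1)
        check_grads(lambda: scalar_sum(ag.add(ag.mul(a, b), a)), [a, b])

    def test_relu_away_from_kink(self):
        rng = np.random.default_rng(1)
        x = rand_tensor(rng, 3, 5)
        x.data[np.abs(x.data) < 0.05] += 0.1  # keep away from nondifferentiable 0
        check_grads(lambda: scalar_sum(ag.relu(x)), [x])

    def test_matmul(self):
        rng = np.random.default_rng(2)
        a = rand_tensor(rng, 4, 3)
        b = rand_tensor(rng, 3, 5)
        check_grads(lambda: scalar_sum(ag.matmul(a, b)), [a, b])

    def test_reshape_concat(self):
        rng = np.random.default_rng(3)
        a = rand_tensor(rng, 1, 2, 3, 3)
        b = rand_tensor(rng, 1, 4, 3, 3)
        check_grads(lambda: scalar_sum(ag.concat([a, b], axis=1)), [a, b])


class TestConvOps:
    def test_conv2d_same_padding_shape_and_grads(self):
        rng = np.random.default_rng(4)
        x = rand_tensor(rng, 2, 3, 5, 5)
        w = rand_tensor(rng, 4, 3, 3, 3)
        b = rand_tensor(rng, 4)
        out = ag.conv2d(x, w, b)
        assert out.shape == (2, 4, 5, 5)
        check_grads(lambda: scalar_sum(ag.conv2d(x, w, b)), [x, w, b])

    def test_conv2d_identity_kernel(self):
        x = ag.Tensor(np.arange(16.0).reshape(1, 1, 4, 4))
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0
        out = ag.conv2d(x, ag.Tensor(w))
        assert np.allclose(out.data, x.data)

    def test_conv_transpose2d_doubles_and_grads(self):
        rng = np.random.default_rng(5)
        x = rand_tensor(rng, 1, 4, 3, 3)
        w = rand_tensor(rng, 4, 2, 2, 2)
        b = rand_tensor(rng, 2)
        out = ag.conv_transpose2d(x, w, b)
        assert out.shape == (1, 2, 6, 6)
        check_grads(lambda: scalar_sum(ag.conv_transpose2d(x, w, b)), [x, w, b])

    def test_conv_transpose_adjoint_of_strided_conv(self):
        # <conv_t(x), y> == <x, conv_strided(y)> for kernel-2 stride-2 pairs
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 2, 3, 3))
        w = rng.normal(size=(2, 1, 2, 2))
        y = rng.normal(size=(1, 1, 6, 6))
        up = ag.conv_transpose2d(ag.Tensor(x), ag.Tensor(w)).data
        # strided conv of y with the same kernel: the adjoint map
        y_blocks = y.reshape(1, 1, 3, 2, 3, 2).transpose(0, 1, 2, 4, 3, 5)
        down = np.einsum("nohwkl,cokl->nchw", y_blocks, w)
        assert np.vdot(up, y) == pytest.approx(np.vdot(x, down), rel=1e-10)


class TestPoolingAndNorm:
    def test_maxpool_grads(self):
        rng = np.random.default_rng(7)
        x = rand_tensor(rng, 1, 2, 6, 6)
        x.data += np.arange(72).reshape(x.shape) * 1e-3  # break argmax ties
        check_grads(lambda: scalar_sum(ag.maxpool2d(x, 2, 2)), [x])

    def test_maxpool_k3_s2_p1_output_size(self):
        x = ag.Tensor(np.zeros((1, 1, 9, 9)))
        assert ag.maxpool2d(x, 3, 2, 1).shape == (1, 1, 5, 5)

    def test_batchnorm_train_grads(self):
        rng = np.random.default_rng(8)
        x = rand_tensor(rng, 4, 3, 2, 2)
        gamma = ag.Tensor(rng.normal(size=3) + 1.5, requires_grad=True)
        beta = rand_tensor(rng, 3)

        def build():
            rm, rv = np.zeros(3), np.ones(3)
            return scalar_sum(ag.batch_norm2d(x, gamma, beta, rm, rv, training=True))

        check_grads(build, [x, gamma, beta], tol=1e-6)

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(9)
        x = rand_tensor(rng, 2, 3, 2, 2)
        gamma = ag.Tensor(np.ones(3), requires_grad=True)
        beta = ag.Tensor(np.zeros(3), requires_grad=True)
        rm = rng.normal(size=3)
        rv = rng.uniform(0.5, 2.0, size=3)
        out = ag.batch_norm2d(x, gamma, beta, rm, rv, training=False)
        expect = (x.data - rm[None, :, None, None]) / np.sqrt(
            rv[None, :, None, None] + 1e-5
        )
        assert np.allclose(out.data, expect)
        check_grads(
            lambda: scalar_sum(
                ag.batch_norm2d(x, gamma, beta, rm.copy(), rv.copy(), training=False)
            ),
            [x, gamma, beta],
        )

    def test_batchnorm_train_output_is_normalized(self):
        rng = np.random.default_rng(10)
        x = ag.Tensor(rng.normal(loc=5, scale=3, size=(8, 2, 4, 4)))
        out = ag.batch_norm2d(
            x, ag.Tensor(np.ones(2)), ag.Tensor(np.zeros(2)), np.zeros(2), np.ones(2),
            training=True,
        )
        assert np.allclose(out.data.mean(axis=(0, 2, 3)), 0, atol=1e-10)
        assert np.allclose(out.data.var(axis=(0, 2, 3)), 1, atol=1e-4)


class TestSoftmaxAndLosses:
    def test_log_softmax_grads_and_normalization(self):
        rng = np.random.default_rng(11)
        x = rand_tensor(rng, 2, 3, 4, 4)
        lp = ag.log_softmax(x, axis=1)
        assert np.allclose(np.exp(lp.data).sum(axis=1), 1.0)
        check_grads(lambda: scalar_sum(ag.log_softmax(x, axis=1)), [x])

    def test_softmax_matches_exp_log_softmax(self):
        rng = np.random.default_rng(12)
        x = rand_tensor(rng, 1, 3, 2, 2)
        assert np.allclose(
            ag.softmax(x, axis=1).data, np.exp(ag.log_softmax(x, axis=1).data)
        )

    def test_nll_loss_grads_and_value(self):
        rng = np.random.default_rng(13)
        x = rand_tensor(rng, 1, 3, 4, 4)
        idx = rng.integers(0, 3, size=(1, 4, 4))
        onehot = np.zeros((1, 3, 4, 4))
        for c in range(3):
            onehot[:, c] = idx == c

        def build():
            return ag.nll_loss(ag.log_softmax(x, axis=1), onehot)

        # value equals mean pixel cross-entropy
        lp = ag.log_softmax(x, axis=1).data
        expect = -(onehot * lp).sum(axis=1).mean()
        assert build().data.item() == pytest.approx(expect)
        check_grads(build, [x])

    def test_dice_loss_op_value_and_grads(self):
        rng = np.random.default_rng(14)
        x = rand_tensor(rng, 1, 2, 3, 3)
        onehot = np.zeros((1, 2, 3, 3))
        idx = rng.integers(0, 2, size=(1, 3, 3))
        onehot[:, 0], onehot[:, 1] = idx == 0, idx == 1

        def build():
            return ag.dice_loss_op(ag.softmax(x, axis=1), onehot)

        q = ag.softmax(x, axis=1).data
        expect = 1 - 2 * (q * onehot).sum() / ((q**2).sum() + (onehot**2).sum())
        assert build().data.item() == pytest.approx(expect)
        check_grads(build, [x], tol=1e-6)


class TestLayersAndOptim:
    def test_state_round_trip(self):
        rng = np.random.default_rng(15)

        class Net(Module):
            def __init__(self):
                super().__init__()
                self.c = Conv2d(1, 2, 3, rng)
                self.bn = BatchNorm2d(2)
                self.up = ConvTranspose2d(2, 1, rng)
                self.fc = Linear(4, 2, rng)

        a, b = Net(), Net()
        assert not np.allclose(a.c.weight.data, b.c.weight.data)
        b.load_state_arrays(a.state_arrays())
        for k, v in a.state_arrays().items():
            assert np.array_equal(v, b.state_arrays()[k]), k

    def test_param_count_conv(self):
        rng = np.random.default_rng(16)
        conv = Conv2d(3, 8, 5, rng)
        assert conv.count_parameters() == 8 * 3 * 5 * 5 + 8

    def test_adam_first_step_magnitude(self):
        # with zero weight decay the first Adam step has magnitude ~lr * sign(g)
        p = ag.Tensor(np.array([1.0, -2.0]), requires_grad=True)
        p.grad = np.array([0.3, -0.7])
        opt = Adam([p], lr=0.01, weight_decay=0.0)
        before = p.data.copy()
        opt.step()
        step = p.data - before
        assert np.allclose(step, -0.01 * np.sign([0.3, -0.7]), atol=1e-6)

    def test_adam_decoupled_weight_decay_direction(self):
        p = ag.Tensor(np.array([10.0]), requires_grad=True)
        p.grad = np.array([0.0])
        opt = Adam([p], lr=0.1, weight_decay=0.5)
        opt.step()
        assert p.data[0] < 10.0  # decay pulls weight toward zero

    def test_adam_converges_on_quadratic(self):
        p = ag.Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.2, weight_decay=0.0)
        for _ in range(300):
            opt.zero_grad()
            p.grad = 2 * p.data  # d/dp ||p||^2
            opt.step()
        assert np.all(np.abs(p.data) < 1e-2)
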