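"""Gradient correctness of the numpy autodiff engine.

Every custom backward pass is checked against central finite differences
(directional derivatives, which average out float32 evaluation noise) or,
for the linear operators, an adjoint dot-product identity.
"""

import numpy as np
import pytest

import wfseg.autodiff as ad
from wfseg.autodiff import Tensor


def directional_check(make_loss, params, rng, eps=3e-3, tol=5e-3):
    """Compare g·d against the symmetric difference quotient along d."""
    loss = make_loss()
    loss.backward()
    grads = [p.grad.copy() for p in params]
    dirs = [rng.normal(size=p.data.shape).astype(np.float32) for p in params]
    analytic = float(sum((g * d).sum() for g, d in zip(grads, dirs)))
    saved = [p.data.copy() for p in params]
    for p, d in zip(params, dirs):
        p.data = p.data + eps * d
    lp = float(make_loss().data)
    for p, s, d in zip(params, saved, dirs):
        p.data = s - eps * d
    lm = float(make_loss().data)
    for p, s in zip(params, saved):
        p.data = s
    fd = (lp - lm) / (2 * eps)
    assert abs(fd - analytic) / max(abs(analytic), 1e-6) < tol, (fd, analytic)


class TestElementwise:
    def test_arithmetic_chain(self, rng):
        x = Tensor(rng.normal(size=(4, 4)).astype(np.float32), requires_grad=True)

        def loss():
            x.grad = None
            y = ad.relu(ad.sub(ad.mul(x, x), Tensor(0.5)))
            return ad.tsum(ad.mul(y, y))

        directional_check(loss, [x], rng)

    def test_sigmoid_softplus_log(self, rng):
        x = Tensor(rng.normal(size=(50,)).astype(np.float32), requires_grad=True)

        def loss():
            x.grad = None
            a = ad.sigmoid(x)
            b = ad.softplus(x)
            return ad.tsum(ad.add(ad.log(ad.add(a, Tensor(0.1))), b))

        directional_check(loss, [x], rng)

    def test_sigmoid_stable_at_extremes(self):
        x = Tensor(np.array([-500.0, 500.0], dtype=np.float32))
        s = ad.sigmoid(x)
        assert np.all(np.isfinite(s.data))
        assert s.data[0] == 0.0 and s.data[1] == 1.0

    def test_softmax_gradient(self, rng):
        x = Tensor(rng.normal(size=(30,)).astype(np.float32), requires_grad=True)
        c = rng.normal(size=(30,)).astype(np.float32)

        def loss():
            x.grad = None
            return ad.tsum(ad.mul(ad.softmax(x), Tensor(c)))

        directional_check(loss, [x], rng)

    def test_broadcast_add_unbroadcasts_grad(self, rng):
        a = Tensor(rng.normal(size=(3, 1, 5)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.normal(size=(5,)).astype(np.float32), requires_grad=True)
        out = ad.tsum(ad.add(a, b))
        out.backward()
        assert a.grad.shape == (3, 1, 5)
        assert b.grad.shape == (5,)
        np.testing.assert_allclose(b.grad, 3.0)


class TestConv3d:
    @pytest.mark.parametrize("stride", [1, 2])
    @pytest.mark.parametrize("k,pad", [(3, 1), (1, 0)])
    def test_gradients(self, rng, stride, k, pad):
        if k == 1 and stride == 2:
            pytest.skip("stride-2 1x1x1 not used in the model")
        x = Tensor(rng.normal(size=(3, 6, 6, 6)).astype(np.float32), requires_grad=True)
        w = Tensor((rng.normal(size=(4, 3, k, k, k)) * 0.2).astype(np.float32), requires_grad=True)
        b = Tensor(np.zeros(4, dtype=np.float32), requires_grad=True)

        def loss():
            for p in (x, w, b):
                p.grad = None
            y = ad.conv3d(x, w, b, stride=stride, padding=pad)
            return ad.tsum(ad.mul(y, y))

        directional_check(loss, [x, w, b], rng)

    def test_output_shapes(self, rng):
        x = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
        w = Tensor(rng.normal(size=(5, 2, 3, 3, 3)).astype(np.float32))
        assert ad.conv3d(x, w, None, stride=1, padding=1).shape == (5, 8, 8, 8)
        assert ad.conv3d(x, w, None, stride=2, padding=1).shape == (5, 4, 4, 4)


class TestNorms:
    def test_group_norm_gradients(self, rng):
        x = Tensor(rng.normal(size=(6, 4, 4, 4)).astype(np.float32), requires_grad=True)
        gamma = Tensor(rng.uniform(0.5, 1.5, 6).astype(np.float32), requires_grad=True)
        beta = Tensor(np.zeros(6, dtype=np.float32), requires_grad=True)
        c = rng.normal(size=(6, 4, 4, 4)).astype(np.float32)

        def loss():
            for p in (x, gamma, beta):
                p.grad = None
            return ad.tsum(ad.mul(ad.group_norm(x, gamma, beta, 3), Tensor(c)))

        directional_check(loss, [x, gamma, beta], rng)

    def test_group_norm_standardizes(self, rng):
        x = Tensor(rng.normal(2.0, 3.0, size=(4, 4, 4, 4)).astype(np.float32))
        out = ad.group_norm(x, Tensor(np.ones(4)), Tensor(np.zeros(4)), 2)
        grouped = out.data.reshape(2, -1)
        np.testing.assert_allclose(grouped.mean(axis=1), 0, atol=1e-5)
        np.testing.assert_allclose(grouped.std(axis=1), 1, atol=1e-3)

    def test_layer_norm_vec_gradients(self, rng):
        x = Tensor(rng.normal(size=(12,)).astype(np.float32), requires_grad=True)
        gamma = Tensor(np.ones(12, dtype=np.float32), requires_grad=True)
        beta = Tensor(np.zeros(12, dtype=np.float32), requires_grad=True)
        c = rng.normal(size=(12,)).astype(np.float32)

        def loss():
            for p in (x, gamma, beta):
                p.grad = None
            return ad.tsum(ad.mul(ad.layer_norm_vec(x, gamma, beta), Tensor(c)))

        directional_check(loss, [x, gamma, beta], rng)


class TestUpsample:
    def test_adjoint_dot_product(self, rng):
        x = rng.normal(size=(2, 4, 4, 4))
        y = rng.normal(size=(2, 8, 8, 8))
        fx = x.copy()
        for axis in (1, 2, 3):
            fx = ad._up1(fx, axis)
        gy = y.copy()
        for axis in (3, 2, 1):
            gy = ad._up1_adjoint(gy, axis)
        assert abs((fx * y).sum() - (x * gy).sum()) < 1e-9

    def test_doubles_each_axis_and_preserves_constants(self):
        x = Tensor(np.full((1, 2, 3, 4), 1.7, dtype=np.float32))
        out = ad.upsample2x(x)
        assert out.shape == (1, 4, 6, 8)
        np.testing.assert_allclose(out.data, 1.7, atol=1e-6)

    def test_gradient(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 4, 4)).astype(np.float32), requires_grad=True)
        c = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)

        def loss():
            x.grad = None
            return ad.tsum(ad.mul(ad.upsample2x(x), Tensor(c)))

        directional_check(loss, [x], rng)


class TestWaveletFusion:
    def test_adjoint_dot_product(self, rng):
        xs = [Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32), requires_grad=True)
              for _ in range(4)]
        f = ad.wavelet_fusion(xs)
        gf = rng.normal(size=f.data.shape).astype(np.float32)
        ad.tsum(ad.mul(f, Tensor(gf))).backward()
        lhs = float((f.data.astype(np.float64) * gf).sum())
        rhs = float(sum((t.data.astype(np.float64) * t.grad).sum() for t in xs))
        assert abs(lhs - rhs) < 1e-4

    def test_forward_matches_reference(self, rng):
        from wfseg.fusion import wavelet_fuse

        stack = rng.normal(size=(4, 2, 8, 8, 8)).astype(np.float32)
        xs = [Tensor(stack[i]) for i in range(4)]
        np.testing.assert_allclose(
            ad.wavelet_fusion(xs).data, wavelet_fuse(stack), atol=1e-6
        )


class TestBackwardMechanics:
    def test_grad_accumulates_over_shared_nodes(self, rng):
        x = Tensor(np.array([2.0], dtype=np.float32), requires_grad=True)
        y = ad.mul(x, x)  # x used twice
        ad.tsum(y).backward()
        np.testing.assert_allclose(x.grad, [4.0])

    def test_backward_requires_scalar(self, rng):
        x = Tensor(rng.normal(size=(3,)).astype(np.float32), requires_grad=True)
        with pytest.raises(ValueError):
            ad.mul(x, x).backward()
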