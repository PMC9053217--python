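"""Autograd engine: gradients vs finite differences, optimizer behaviour."""

import numpy as np
import pytest

from ischeseg import nn
from ischeseg.nn import tensor as T


def _fd_check(f, x_data, rng, eps=1e-3, tol=5e-2, n_probes=5):
    """Compare backward() against central finite differences at random
    entries (float32 arithmetic, hence the loose tolerance)."""
    x = T.Tensor(x_data.astype(np.float32), requires_grad=True)
    out = f(x)
    w = rng.normal(size=out.data.shape).astype(np.float32)
    out.backward(w)
    for _ in range(n_probes):
        ix = tuple(rng.integers(0, s) for s in x_data.shape)
        xp = x_data.copy(); xp[ix] += eps
        xm = x_data.copy(); xm[ix] -= eps
        num = ((f(T.Tensor(xp.astype(np.float32))).data
                - f(T.Tensor(xm.astype(np.float32))).data) * w).sum() / (2 * eps)
        assert x.grad[ix] == pytest.approx(num, rel=tol, abs=5e-3)


@pytest.fixture()
def x5(rng):
    return rng.normal(size=(2, 3, 6, 8, 4))


class TestGradients:
    def test_conv3d(self, rng, x5):
        conv = nn.Conv3d(3, 5, 3)
        _fd_check(lambda t: T.conv3d(t, conv.weight, conv.bias), x5, rng)

    def test_conv3d_matches_direct_convolution(self, rng):
        x = rng.normal(size=(1, 2, 4, 5, 3)).astype(np.float32)
        conv = nn.Conv3d(2, 3, 3)
        out = T.conv3d(T.Tensor(x), conv.weight, conv.bias).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        for co in range(3):
            ref = np.zeros((4, 5, 3))
            for ci in range(2):
                for dz in range(3):
                    for dy in range(3):
                        for dx in range(3):
                            ref += (conv.weight.data[co, ci, dz, dy, dx]
                                    * xp[0, ci, dz:dz + 4, dy:dy + 5,
                                         dx:dx + 3])
            np.testing.assert_allclose(out[0, co],
                                       ref + conv.bias.data[co], atol=1e-4)

    def test_conv_transpose(self, rng, x5):
        tc = nn.ConvTranspose3d(3, 4, 2)
        _fd_check(lambda t: T.conv_transpose3d(t, tc.weight, tc.bias, 2),
                  x5, rng)

    def test_pooling_and_global_ops(self, rng, x5):
        for op in (T.maxpool3d, T.avgpool3d, T.global_avg_pool,
                   T.global_max_pool, T.channel_max, T.channel_mean):
            _fd_check(op, x5, rng, n_probes=3)

    def test_activations(self, rng, x5):
        x = x5.copy()
        x[np.abs(x) < 0.05] += 0.2    # keep probes away from the SeLU kink
        _fd_check(T.selu, x, rng)
        _fd_check(T.sigmoid, x5, rng)

    def test_batchnorm_training_mode(self, rng, x5):
        bn = nn.BatchNorm3d(3)
        _fd_check(lambda t: T.batchnorm(t, bn.gamma, bn.beta,
                                        dict(bn.running), True), x5, rng)

    def test_upsample_is_exact_adjoint(self, rng):
        # the op is linear: its backward must be the exact matrix transpose
        x0 = np.zeros((1, 1, 2, 2, 2), dtype=np.float32)
        n_in = x0.size
        n_out = T.upsample2x_linear(T.Tensor(x0)).data.size
        fwd = np.zeros((n_out, n_in))
        adj = np.zeros((n_out, n_in))
        for i in range(n_in):
            e = np.zeros(n_in, dtype=np.float32); e[i] = 1
            fwd[:, i] = T.upsample2x_linear(
                T.Tensor(e.reshape(x0.shape))).data.ravel()
        for o in range(n_out):
            g = np.zeros(n_out, dtype=np.float32); g[o] = 1
            xt = T.Tensor(x0, requires_grad=True)
            T.upsample2x_linear(xt).backward(g.reshape(1, 1, 4, 4, 4))
            adj[o] = xt.grad.ravel()
        np.testing.assert_array_equal(fwd, adj)
        np.testing.assert_allclose(fwd.sum(axis=1), 1.0)  # interpolation

    def test_dense_and_weight_grads(self, rng):
        d = rng.normal(size=(4, 7))
        dl = nn.Dense(7, 3)
        _fd_check(lambda t: T.dense(t, dl.weight, dl.bias), d, rng)

    def test_backward_multi_equals_separate_sweeps(self, rng):
        conv = nn.Conv3d(2, 2, 3)
        x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)

        def run(multi):
            conv.zero_grad()
            xt = T.Tensor(x)
            a = T.conv3d(xt, conv.weight, conv.bias)
            b = T.selu(a)
            ga = np.ones_like(a.data)
            gb = 0.5 * np.ones_like(b.data)
            if multi:
                T.backward_multi([(a, ga), (b, gb)])
            else:
                a.backward(ga)
                a.zero_grad()   # clear the seed before the second sweep
                b.backward(gb)
            return conv.weight.grad.copy()

        np.testing.assert_allclose(run(True), run(False), rtol=1e-4,
                                   atol=1e-5)


class TestModules:
    def test_parameters_found_in_nested_containers(self):
        class Holder(nn.Module):
            def __init__(self):
                self.items = [[nn.Conv3d(1, 1, 3)], (nn.Dense(2, 2),)]

        params = Holder().parameters()
        assert len(params) == 4  # two weights + two biases

    def test_state_dict_round_trip(self, rng):
        a = nn.ConvBlock(2, 3)
        b = nn.ConvBlock(2, 3)
        b.load_state_dict(a.state_dict())
        x = T.Tensor(rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32))
        a.eval(), b.eval()
        np.testing.assert_array_equal(a(x).data, b(x).data)

    def test_save_load_file(self, tmp_path, rng):
        a = nn.ConvBlock(1, 2)
        path = tmp_path / "ckpt.npz"
        a.save(path)
        b = nn.ConvBlock(1, 2)
        b.load(path)
        x = T.Tensor(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        a.eval(), b.eval()
        np.testing.assert_array_equal(a(x).data, b(x).data)


class TestOptim:
    def test_adam_minimizes_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            p.grad = 2.0 * p.data  # d/dp of ||p||^2
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_plateau_schedule_halves_after_patience(self):
        p = nn.Parameter(np.zeros(1, dtype=np.float32))
        opt = nn.Adam([p], lr=3e-4)
        sched = nn.ReduceLROnPlateau(opt, patience=5, min_lr=1e-5)
        sched.step(1.0)            # establishes the best loss
        for _ in range(4):
            sched.step(1.0)
            assert opt.lr == pytest.approx(3e-4)
        sched.step(1.0)            # fifth stagnant epoch
        assert opt.lr == pytest.approx(1.5e-4)

    def test_plateau_floor(self):
        p = nn.Parameter(np.zeros(1, dtype=np.float32))
        opt = nn.Adam([p], lr=2e-5)
        sched = nn.ReduceLROnPlateau(opt, patience=1, min_lr=1e-5)
        for _ in range(10):
            sched.step(1.0)
        assert opt.lr == pytest.approx(1e-5)

    def test_improvement_resets_patience(self):
        p = nn.Parameter(np.zeros(1, dtype=np.float32))
        opt = nn.Adam([p], lr=3e-4)
        sched = nn.ReduceLROnPlateau(opt, patience=5)
        losses = [1.0, 0.99, 0.98, 0.97, 0.96, 0.95, 0.94]
        for lo in losses:
            sched.step(lo)
        assert opt.lr == pytest.approx(3e-4)
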