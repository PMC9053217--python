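"""A minimal reverse-mode autograd over float32 NumPy arrays.

Only what volumetric segmentation networks need: 3D convolution (im2col +
BLAS matmul), non-overlapping transposed convolution, 2x pooling, global
pooling, dense layers, batch normalization, SeLU/sigmoid, concatenation and
broadcast arithmetic.  Tensors record their parents and a backward closure;
``backward()`` runs a topological sweep accumulating gradients.

Arrays are channel-first: (N, C, D, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concat", "add", "mul", "conv3d", "conv_transpose3d",
    "maxpool3d", "avgpool3d", "global_avg_pool", "global_max_pool",
    "dense", "batchnorm", "selu", "sigmoid", "upsample2x_linear", "reshape",
    "backward_multi",
]

F32 = np.float32


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=F32).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse sweep from this node; seeds with ones if no grad given."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=F32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def backward_multi(seeds):
    """Backward from several roots in one topological sweep.

    ``seeds`` is a list of (tensor, gradient) pairs; gradients accumulate
    exactly as if the roots were summed into one scalar loss.
    """
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p in t._parents:
            visit(p)
        topo.append(t)

    for root, grad in seeds:
        visit(root)
        root._accum(np.asarray(grad, dtype=F32))
    for t in reversed(topo):
        if t._backward is not None and t.grad is not None:
            t._backward(t.grad)


def _needs(*tensors):
    return any(t.requires_grad for t in tensors)


def _wrap(data, parents, backward):
    req = _needs(*[p for p in parents if isinstance(p, Tensor)])
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _wrap(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _wrap(out_data, (a, b), backward)


def _unbroadcast(g, shape):
    """Sum g down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(x.data.shape))

    return _wrap(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return _wrap(out_data, tuple(tensors), backward)


# ------------------------------------------------------------- convolutions

def _taps(k):
    return [(dz, dy, dx) for dz in range(k) for dy in range(k)
            for dx in range(k)]


def _im2col(x: np.ndarray, k: int):
    """(N, C, D, H, W) -> (C*k^3, N*D*H*W) channel-major patch matrix
    ('same' padding).  Built tap by tap: each kernel offset is one cheap
    strided copy rather than a single high-dimensional gather."""
    p = k // 2
    n, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    cols = np.empty((c, k ** 3, n, d, h, w), dtype=F32)
    for t, (dz, dy, dx) in enumerate(_taps(k)):
        np.copyto(cols[:, t],
                  xp[:, :, dz:dz + d, dy:dy + h, dx:dx + w].transpose(
                      1, 0, 2, 3, 4))
    return cols.reshape(c * k ** 3, n * d * h * w)


def _col2im(gcols: np.ndarray, shape, k: int):
    """Scatter-add transpose of :func:`_im2col`."""
    n, c, d, h, w = shape
    p = k // 2
    gxp = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=F32)
    g = gcols.reshape(c, k ** 3, n, d, h, w)
    for t, (dz, dy, dx) in enumerate(_taps(k)):
        gxp[:, :, dz:dz + d, dy:dy + h, dx:dx + w] += \
            g[:, t].transpose(1, 0, 2, 3, 4)
    if p == 0:
        return gxp
    return gxp[:, :, p:-p, p:-p, p:-p]


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, 'same'-padded 3D convolution. w: (Cout, Cin, k, k, k)."""
    n, cin, d, h, wd = x.data.shape
    cout, cin_w, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    cols = _im2col(x.data, k)                      # (Cin k^3, Nvox)
    wmat = w.data.reshape(cout, cin * k ** 3)      # (Cout, Cin k^3)
    out = wmat @ cols                              # (Cout, Nvox)
    if b is not None:
        out += b.data[:, None]
    out_data = np.ascontiguousarray(
        out.reshape(cout, n, d, h, wd).transpose(1, 0, 2, 3, 4))

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(
            cout, -1)                              # (Cout, Nvox)
        if w.requires_grad:
            w._accum((gmat @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=1))
        if x.requires_grad:
            gcols = wmat.T @ gmat                  # (Cin k^3, Nvox)
            x._accum(_col2im(gcols, x.data.shape, k))

    parents = (x, w) if b is None else (x, w, b)
    return _wrap(out_data, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Non-overlapping transposed conv: kernel size == stride.

    w: (Cin, Cout, s, s, s).  Each input voxel paints an s^3 output block,
    so the output is exactly ``stride`` times larger per axis.
    """
    n, cin, d, h, wd = x.data.shape
    cin_w, cout, s = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin != cin_w or s != stride:
        raise ValueError("kernel does not match input channels / stride")
    xm = x.data.transpose(0, 2, 3, 4, 1).reshape(-1, cin)     # (Nvox, Cin)
    wmat = w.data.reshape(cin, cout * s ** 3)
    out = xm @ wmat                                            # (Nvox, Cout s^3)
    out = out.reshape(n, d, h, wd, cout, s, s, s)
    out_data = np.zeros((n, cout, d * s, h * s, wd * s), dtype=F32)
    for dz in range(s):
        for dy in range(s):
            for dx in range(s):
                out_data[:, :, dz::s, dy::s, dx::s] = \
                    out[:, :, :, :, :, dz, dy, dx].transpose(0, 4, 1, 2, 3)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)

    def backward(g):
        gb = np.empty((n, d, h, wd, cout, s, s, s), dtype=F32)
        for dz in range(s):
            for dy in range(s):
                for dx in range(s):
                    gb[:, :, :, :, :, dz, dy, dx] = \
                        g[:, :, dz::s, dy::s, dx::s].transpose(0, 2, 3, 4, 1)
        gmat = gb.reshape(-1, cout * s ** 3)                   # (Nvox, Cout s^3)
        if w.requires_grad:
            w._accum((xm.T @ gmat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gx = (gmat @ wmat.T).reshape(n, d, h, wd, cin)
            x._accum(gx.transpose(0, 4, 1, 2, 3))

    parents = (x, w) if b is None else (x, w, b)
    return _wrap(out_data, parents, backward)


# ------------------------------------------------------------------ pooling

def _pool_view(x: np.ndarray):
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"2x pooling needs even spatial dims, got {x.shape}")
    return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)


def maxpool3d(x: Tensor) -> Tensor:
    v = _pool_view(x.data)
    out_data = v.max(axis=(3, 5, 7))

    def backward(g):
        if x.requires_grad:
            mask = v == out_data[:, :, :, None, :, None, :, None]
            # split ties evenly so the total incoming gradient is conserved
            counts = mask.sum(axis=(3, 5, 7), keepdims=True)
            gx = mask * (g[:, :, :, None, :, None, :, None] / counts)
            x._accum(gx.reshape(x.data.shape))

    return _wrap(out_data, (x,), backward)


def avgpool3d(x: Tensor) -> Tensor:
    v = _pool_view(x.data)
    out_data = v.mean(axis=(3, 5, 7))

    def backward(g):
        if x.requires_grad:
            gx = np.broadcast_to(g[:, :, :, None, :, None, :, None] / 8.0,
                                 v.shape)
            x._accum(np.ascontiguousarray(gx).reshape(x.data.shape))

    return _wrap(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C)."""
    nvox = np.prod(x.data.shape[2:])
    out_data = x.data.mean(axis=(2, 3, 4))

    def backward(g):
        if x.requires_grad:
            gx = np.broadcast_to((g / nvox)[:, :, None, None, None],
                                 x.data.shape)
            x._accum(np.ascontiguousarray(gx))

    return _wrap(out_data, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C)."""
    flat = x.data.reshape(*x.data.shape[:2], -1)
    idx = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(flat)
            np.put_along_axis(gx, idx[:, :, None], g[:, :, None], axis=2)
            x._accum(gx.reshape(x.data.shape))

    return _wrap(out_data, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """Max over channels: (N, C, D, H, W) -> (N, 1, D, H, W)."""
    idx = x.data.argmax(axis=1)[:, None]
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, idx, g, axis=1)
            x._accum(gx)

    return _wrap(out_data, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    """Mean over channels: (N, C, D, H, W) -> (N, 1, D, H, W)."""
    c = x.data.shape[1]
    out_data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g / c, x.data.shape).copy())

    return _wrap(out_data, (x,), backward)


# -------------------------------------------------------------- dense & norm

def dense(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (N, Cin), w: (Cin, Cout)."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        if w.requires_grad:
            w._accum(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))
        if x.requires_grad:
            x._accum(g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return _wrap(out, parents, backward)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
              training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W).

    ``running`` carries 'mean'/'var' state updated in training mode and
    used verbatim at inference.
    """
    axes = (0, 2, 3, 4)
    shape = (1, x.data.shape[1], 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            if training:
                m = float(np.prod([x.data.shape[a] for a in axes]))
                gxhat = g * gamma.data.reshape(shape)
                t1 = gxhat.sum(axis=axes, keepdims=True)
                t2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
                gx = (inv.reshape(shape) / m) * (m * gxhat - t1 - xhat * t2)
            else:
                gx = g * (gamma.data * inv).reshape(shape)
            x._accum(gx.astype(F32))

    return _wrap(out, (x, gamma, beta), backward)


# -------------------------------------------------------------- activations

_SELU_LAMBDA = F32(1.0507009873554805)
_SELU_ALPHA = F32(1.6732632423543772)


def selu(x: Tensor) -> Tensor:
    pos = x.data > 0
    expx = np.exp(np.minimum(x.data, 0.0))
    out = _SELU_LAMBDA * np.where(pos, x.data, _SELU_ALPHA * (expx - 1.0))

    def backward(g):
        if x.requires_grad:
            dx = np.where(pos, _SELU_LAMBDA, _SELU_LAMBDA * _SELU_ALPHA * expx)
            x._accum(g * dx)

    return _wrap(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # clamp the preactivation so float32 exp cannot overflow
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def backward(g):
        if x.requires_grad:
            x._accum(g * out * (1.0 - out))

    return _wrap(out, (x,), backward)


# ---------------------------------------------------------------- upsampling

def _linear_axis_weights(n_out: int):
    """2x linear upsampling taps along one axis (half-voxel aligned)."""
    c = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(c).astype(int), 0, n_out // 2 - 1)
    i1 = np.clip(i0 + 1, 0, n_out // 2 - 1)
    w1 = np.clip(c - i0, 0.0, 1.0).astype(F32)
    return i0, i1, (1.0 - w1), w1


def upsample2x_linear(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of (N, C, D, H, W)."""
    data = x.data
    taps = []
    for ax in (2, 3, 4):
        n_out = data.shape[ax] * 2
        i0, i1, w0, w1 = _linear_axis_weights(n_out)
        sh = [1] * 5
        sh[ax] = n_out
        data = (np.take(data, i0, axis=ax) * w0.reshape(sh)
                + np.take(data, i1, axis=ax) * w1.reshape(sh))
        taps.append((ax, i0, i1, w0, w1))

    def backward(g):
        if not x.requires_grad:
            return
        for ax, i0, i1, w0, w1 in reversed(taps):
            sh = [1] * 5
            sh[ax] = g.shape[ax]
            n_in = g.shape[ax] // 2
            gi = np.zeros(g.shape[:ax] + (n_in,) + g.shape[ax + 1:], dtype=F32)
            np.add.at(gi, _axis_index(ax, i0), g * w0.reshape(sh))
            np.add.at(gi, _axis_index(ax, i1), g * w1.reshape(sh))
            g = gi
        x._accum(g)

    return _wrap(data, (x,), backward)


def _axis_index(ax, idx):
    sl = [slice(None)] * 5
    sl[ax] = idx
    return tuple(sl)
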