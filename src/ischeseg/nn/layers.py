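"""Layer modules over the autograd core: parameters, init, (de)serialization.

Initialization is LeCun-normal (fan-in scaled), the self-normalizing choice
that pairs with SeLU activations.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Conv3d", "ConvTranspose3d", "Dense",
           "BatchNorm3d", "ConvBlock", "rng_init"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


_GLOBAL_RNG = np.random.default_rng(0)


def rng_init(seed: int | None):
    """Set the generator used for weight initialization."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)
    return _GLOBAL_RNG


class Module:
    """Minimal module container with recursive parameter discovery."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params, seen = [], set()
        for _, value in self._children():
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
            elif isinstance(value, Module):
                for p in value.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
        return params

    def _children(self):
        def walk(name, value):
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    yield from walk(f"{name}.{i}", v)

        for name, value in vars(self).items():
            yield from walk(name, value)

    def named_parameters(self, prefix: str = ""):
        for name, value in self._children():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            else:
                yield from value.named_parameters(prefix=full + ".")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            if isinstance(child, Module):
                child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ---- checkpointing ----
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self._walk_modules():
            if isinstance(mod, BatchNorm3d):
                state[f"{name}.running_mean"] = mod.running["mean"].copy()
                state[f"{name}.running_var"] = mod.running["var"].copy()
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.ascontiguousarray(state[name], dtype=np.float32)
        for name, mod in self._walk_modules():
            if isinstance(mod, BatchNorm3d):
                mod.running["mean"] = np.asarray(state[f"{name}.running_mean"])
                mod.running["var"] = np.asarray(state[f"{name}.running_var"])
        return self

    def _walk_modules(self, prefix: str = ""):
        for name, value in self._children():
            if isinstance(value, Module):
                full = f"{prefix}{name}"
                yield full, value
                yield from value._walk_modules(prefix=full + ".")

    def save(self, path):
        np.savez_compressed(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as zf:
            self.load_state_dict({k: zf[k] for k in zf.files})
        return self


def _lecun_normal(shape, fan_in):
    std = np.sqrt(1.0 / fan_in)
    return _GLOBAL_RNG.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    """Stride-1 'same' 3D convolution with optional bias."""

    def __init__(self, cin: int, cout: int, k: int = 3, bias: bool = True):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k ** 3
        self.weight = Parameter(_lecun_normal((cout, cin, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Non-overlapping transposed conv (kernel == stride): learned unpooling."""

    def __init__(self, cin: int, cout: int, stride: int = 2, bias: bool = True):
        self.cin, self.cout, self.stride = cin, cout, stride
        self.weight = Parameter(_lecun_normal(
            (cin, cout, stride, stride, stride), cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class Dense(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True):
        self.cin, self.cout = cin, cout
        self.weight = Parameter(_lecun_normal((cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.dense(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running = {"mean": np.zeros(c, dtype=np.float32),
                        "var": np.ones(c, dtype=np.float32)}

    def __call__(self, x: Tensor) -> Tensor:
        return T.batchnorm(x, self.gamma, self.beta, self.running,
                           training=self.training, momentum=self.momentum,
                           eps=self.eps)


class ConvBlock(Module):
    """Two consecutive 3^3 conv + batch-norm + SeLU layers."""

    def __init__(self, cin: int, cout: int, k: int = 3):
        self.conv1 = Conv3d(cin, cout, k)
        self.bn1 = BatchNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, k)
        self.bn2 = BatchNorm3d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        x = T.selu(self.bn1(self.conv1(x)))
        return T.selu(self.bn2(self.conv2(x)))
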