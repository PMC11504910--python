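"""Lightweight neural-network layers and the Adam optimizer.

Layers follow the familiar Module pattern: parameters are :class:`Tensor`
objects with ``requires_grad=True``; ``train()``/``eval()`` toggle
behaviour of Dropout and BatchNorm; ``state_dict``/``load_state_dict``
serialise parameters and running buffers by dotted name.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    conv2d,
    depthwise_conv2d,
    default_dtype,
)


class Module:
    """Base class: attribute traversal gives parameters, submodules, buffers."""

    def __init__(self):
        self.training = True
        self._buffer_names: list[str] = []

    # traversal is over sorted attribute names so ordering is deterministic
    def _children(self):
        for name in sorted(vars(self)):
            val = getattr(self, name)
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            val = getattr(self, name)
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def register_buffer(self, name: str, value: np.ndarray):
        setattr(self, name, value)
        self._buffer_names.append(name)

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: np.asarray(v).copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for k, v in params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype).copy()
        own = {k for k, _ in self.named_buffers()}
        for k in own:
            parts = k.split(".")
            obj = self
            for p in parts[:-1]:
                obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
            cur = getattr(obj, parts[-1])
            setattr(obj, parts[-1], np.asarray(state[k], dtype=cur.dtype).copy())

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(default_dtype())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=default_dtype()),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """Standard or depthwise 2-D convolution (NCHW)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 depthwise: bool = False, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        self.depthwise = depthwise
        if depthwise:
            if out_channels != in_channels:
                raise ValueError("depthwise conv requires out_channels == in_channels")
            fan_in = kernel * kernel
            self.weight = Tensor(
                _he_init(rng, (in_channels, kernel, kernel), fan_in),
                requires_grad=True)
        else:
            fan_in = in_channels * kernel * kernel
            self.weight = Tensor(
                _he_init(rng, (out_channels, in_channels, kernel, kernel), fan_in),
                requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=default_dtype()),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.depthwise:
            return depthwise_conv2d(x, self.weight, self.bias,
                                    self.stride, self.padding)
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features, dtype=default_dtype()),
                            requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=default_dtype()),
                           requires_grad=True)
        self.register_buffer("running_mean",
                             np.zeros(num_features, dtype=default_dtype()))
        self.register_buffer("running_var",
                             np.ones(num_features, dtype=default_dtype()))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the last dimension of the input."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=default_dtype()), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=default_dtype()), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        xhat = centred * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; active only in training mode. Seeded per instance."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))


class Adam:
    """Adam optimizer (Kingma & Ba defaults: beta 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
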