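"""Neural-network layers, parameter containers and optimizers.

Layers follow the usual Module convention: submodules and parameters are
registered on attribute assignment, ``parameters()`` walks the tree, and
``train()``/``eval()`` toggle batch-norm/dropout behaviour.  Weight
initialization is Kaiming-uniform for convolution and dense kernels, zeros
for biases and ones/zeros for normalization scales/shifts, drawn from a
process-global generator seeded with :func:`manual_seed`.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_global_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for weight init and dropout masks."""
    global _global_rng
    _global_rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _global_rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_uniform(shape: tuple[int, ...], fan_in: int) -> Parameter:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return Parameter(_global_rng.uniform(-bound, bound, size=shape).astype(np.float32))


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state --------------------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._parameters.items():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            out[prefix + name] = np.array(getattr(self, name), copy=True)
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._parameters.items():
            p.data = np.array(state[prefix + name], dtype=np.float32, copy=True)
        for name in self._buffers:
            buf = np.array(state[prefix + name], copy=True)
            self._buffers[name] = buf
            object.__setattr__(self, name, buf)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


# -- basic layers ------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size, stride=1,
                 padding=0, dilation=1, groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = ag._pair(kernel_size)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_channels // groups) * kh * kw
        self.weight = kaiming_uniform((out_channels, in_channels // groups, kh, kw), fan_in)
        self.bias = kaiming_uniform((out_channels,), fan_in) if bias else None
        if bias:
            self.bias.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = kaiming_uniform((out_features, in_features), in_features)
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization with bias-corrected running statistics.

    Training batches update an exponential moving average of the batch
    mean/variance; at evaluation the EMA is divided by ``1 - (1-m)^t``
    (t = batches seen), so the statistics are a proper weighted average of
    what was actually observed rather than being pulled toward the
    arbitrary zero/one initialization — this matters for short runs, where
    an uncorrected EMA is still dominated by its cold start.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features, self.eps, self.momentum = num_features, eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("num_batches", np.zeros(1, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean *= (1 - m)
            self.running_mean += m * mu.data.reshape(-1)
            self.running_var *= (1 - m)
            self.running_var += m * unbiased
            self.num_batches += 1
        else:
            t = float(self.num_batches[0])
            corr = 1.0 - (1.0 - self.momentum) ** t if t > 0 else 1.0
            mean_hat = self.running_mean / corr if t > 0 else self.running_mean
            var_hat = self.running_var / corr if t > 0 else np.ones_like(self.running_var)
            mu = Tensor(mean_hat.reshape(1, -1, 1, 1))
            var = Tensor(var_hat.reshape(1, -1, 1, 1))
        # fold into per-channel scale/shift so only two full-size ops run
        c = self.num_features
        scale = self.weight.reshape(1, c, 1, 1) / ((var + self.eps).sqrt())
        shift = self.bias.reshape(1, c, 1, 1) - mu * scale
        return x * scale + shift


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Hardsigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hardsigmoid()


class Hardswish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hardswish()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (_global_rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class ConvBNAct(Module):
    """Convolution -> batch norm -> activation, bias-free (bias folds into BN)."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, groups=1,
                 dilation=1, act: str = "relu"):
        super().__init__()
        kh, _ = ag._pair(kernel_size)
        pad = (kh - 1) // 2 * (dilation if isinstance(dilation, int) else dilation[0])
        self.conv = Conv2d(in_channels, out_channels, kernel_size, stride=stride,
                           padding=pad, dilation=dilation, groups=groups, bias=False)
        self.bn = BatchNorm2d(out_channels)
        self.act = {"relu": ReLU(), "hardswish": Hardswish(), "none": Identity()}[act]

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


# -- optimizers --------------------------------------------------------------

class Optimizer:
    def __init__(self, params, lr: float, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _grad(self, p: Parameter) -> np.ndarray:
        g = p.grad
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = self._grad(p)
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.betas, self.eps = betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = self._grad(p)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSProp(Optimizer):
    def __init__(self, params, lr: float = 1e-4, alpha: float = 0.99, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.alpha, self.eps = alpha, eps
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = self._grad(p)
            s *= self.alpha
            s += (1 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)


def make_optimizer(name: str, params, lr: float, weight_decay: float = 0.0) -> Optimizer:
    name = name.upper()
    if name == "ADAM":
        return Adam(params, lr=lr, weight_decay=weight_decay)
    if name == "SGD":
        return SGD(params, lr=lr, weight_decay=weight_decay)
    if name == "RMSPROP":
        return RMSProp(params, lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")
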