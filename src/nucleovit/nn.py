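"""Neural-network building blocks and the Adam optimizer.

Thin layer over :mod:`nucleovit.autograd`; the API loosely follows the
conventions of mainstream deep-learning frameworks so the model code reads
familiarly.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, maxpool2d

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "MaxPool2d", "ReLU", "GELU",
    "Dropout", "LayerNorm", "ModuleList", "Sequential", "softmax",
    "log_softmax", "cross_entropy", "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container tracking parameters and submodules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode=True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, module):
        setattr(self, str(len(self._list)), module)
        self._list.append(module)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)

    def __iter__(self):
        return iter(self._list)


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


def _kaiming(rng, fan_in, shape):
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (in_features, out_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """3x3-style stride-1 convolution (stride handled by pooling layers)."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 padding=0, groups=1, bias=True):
        super().__init__()
        fan_in = in_channels // groups * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(
            rng, fan_in, (out_channels, in_channels // groups, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.padding = padding
        self.groups = groups
        self._capture = False
        self.activation: Tensor | None = None

    def forward(self, x):
        out = conv2d(x, self.weight, self.bias, padding=self.padding,
                     groups=self.groups)
        if self._capture:
            self.activation = out
        return out


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._capture = False
        self.activation: Tensor | None = None

    def forward(self, x):
        out = maxpool2d(x, self.kernel_size, self.stride, self.padding)
        if self._capture:
            self.activation = out
        return out


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    """tanh approximation of GELU."""

    def forward(self, x):
        inner = 0.7978845608028654 * (x + 0.044715 * x * x * x)
        return 0.5 * x * (1.0 + inner.tanh())


class Dropout(Module):
    def __init__(self, p, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xhat = centered * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


def softmax(x: Tensor, axis=-1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis=-1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; logits (N, K), labels int (N,)."""
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
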