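"""Neural-network modules built on the autodiff engine.

The Module protocol mirrors the familiar define-by-run style: parameters
are :class:`~raecg.nn.autodiff.Tensor` objects with ``requires_grad=True``,
``module(x)`` runs the forward pass, and ``module.train()`` /
``module.eval()`` toggle batch-statistic behaviour.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Upsample",
    "group_norm",
    "softmax",
    "cross_entropy",
    "concat",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for name, m in self._named_buffers().items():
            out[name] = m.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self._named_buffers()
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=np.float32)
            elif k in buffers:
                buffers[k][...] = v
            else:
                raise KeyError(f"unknown parameter {k!r} in state dict")

    def _named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for attr in getattr(self, "_buffer_names", ()):
            out[prefix + attr] = getattr(self, attr)
        for name, m in self._modules.items():
            out.update(m._named_buffers(prefix + name + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution via im2col.

    Weights are drawn uniform in [-1/sqrt(fan_in), 1/sqrt(fan_in)]: the
    conservative bound keeps the residual-attention stack's multiplicative
    shortcut/attention chains from inflating activations at init.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (out_ch, fan_in)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, w = x.shape[2], x.shape[3]
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        ow = (w + 2 * self.pad - self.k) // self.stride + 1
        cols = x.im2col(self.k, self.k, self.stride, self.pad)  # (N, C*k*k, OH*OW)
        out = self.weight @ cols  # (N, out_ch, OH*OW) via broadcasting
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_ch, 1)
        return out.reshape(n, self.out_ch, oh, ow)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_f)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int, pad: int = 0):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2d(self.k, self.stride, self.pad)


class GlobalAvgPool2d(Module):
    """Average over the full spatial extent -> (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Upsample(Module):
    """Bilinear upsampling to a fixed target size."""

    def __init__(self, size: tuple[int, int]):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return x.bilinear_resize(*self.size)


def group_norm(x: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalisation without affine parameters (those live in the caller)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    g = x.reshape(n, groups, (c // groups) * h * w)
    mu = g.mean(axis=2, keepdims=True)
    var = ((g - mu) ** 2.0).mean(axis=2, keepdims=True)
    out = (g - mu) * ((var + eps) ** -0.5)
    return out.reshape(n, c, h, w)


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically-stable softmax along `axis`."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant w.r.t. grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class targets against raw scores."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    picked = p[np.arange(n), np.asarray(targets, dtype=np.int64)]
    return -(picked + 1e-12).log().mean()
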