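"""Layer modules: parameter containers with a ``forward`` method.

Parameters are initialised from an explicit ``numpy.random.Generator`` so
that network construction is reproducible; there is no global RNG state.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor, as_tensor, grad_enabled


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k in self._buffers:
            yield prefix + k, self._buffers[k]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            out["buffer:" + name] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = state[name].copy()
        for name, val in state.items():
            if name.startswith("buffer:"):
                self._set_buffer(name[len("buffer:"):], val.copy())

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        mod: Module = self
        for p in parts[:-1]:
            mod = mod._modules[p]
        mod._buffers[parts[-1]] = value

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding derived from kernel/dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, dilation: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)
        self.dilation = dilation
        self.padding = ((kh - 1) * dilation // 2, (kw - 1) * dilation // 2)
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, kh, kw),
                                         in_channels * kh * kw))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        padding=self.padding, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """Kernel-2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (in_channels, out_channels, 2, 2),
                                         in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d_2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        out_data = x.data @ self.weight.data.T + self.bias.data
        w, b = self.weight, self.bias

        def backward(g):
            if b.requires_grad:
                b._accumulate(g.sum(axis=0))
            if w.requires_grad:
                w._accumulate(g.T @ x.data)
            if x.requires_grad:
                x._accumulate(g @ w.data)

        return Tensor._node(out_data, (x, w, b), backward)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics (and updates the running
    estimates); eval mode uses the running estimates, so inference is a
    deterministic function of the input alone.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self._buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self._buffers["running_var"] = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        shape = (1, -1, 1, 1)
        if self.training and grad_enabled():
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mean.data.reshape(-1)
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * unbiased
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mean = self._buffers["running_mean"].reshape(shape)
            var = self._buffers["running_var"].reshape(shape)
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        from .tensor import relu
        return relu(x)
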