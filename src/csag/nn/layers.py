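"""Module/parameter containers and the layers used by the segmentation nets."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor, bilinear_resize, conv2d

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Sequential",
    "ReLU",
    "Upsample",
    "softmax_channels",
]


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Tiny torch-like module: tracks sub-modules and parameters by attribute."""

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

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for key, (owner, attr) in self._all_buffers().items():
            state[key] = getattr(owner, attr).copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = self._all_buffers()
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict is missing keys: {sorted(missing)[:5]}")
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {params[key].data.shape} vs {value.shape}")
                params[key].data = value.astype(params[key].data.dtype, copy=True)
            elif key in buffers:
                owner, attr = buffers[key]
                setattr(owner, attr, value.copy())
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def _buffers(self) -> dict:
        return {}

    def _all_buffers(self, prefix: str = "") -> dict:
        out = {prefix + k: (self, k) for k in self._buffers()}
        for name, m in self._modules.items():
            out.update(m._all_buffers(prefix + name + "."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(fan_in: int, shape: tuple, rng: np.random.Generator, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, bias: bool = True, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k, self.pad = k, (k // 2 if pad is None else pad)
        self.weight = Parameter(_kaiming(cin * k * k, (cout, cin, k, k), rng, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Parameter(_kaiming(cin, (cin, cout), rng, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def forward(self, x):
        y = as_tensor(x) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        x = as_tensor(x)
        c = x.shape[1]
        if self.training:
            from .tensor import batch_norm_train

            out, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            n = x.size // c
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            return out
        mu = self.running_mean.reshape(1, c, 1, 1).astype(x.dtype)
        sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1).astype(x.dtype)
        xhat = (x - Tensor(mu)) / Tensor(sd)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x):
        return as_tensor(x).relu()


class Upsample(Module):
    def __init__(self, scale: int):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        x = as_tensor(x)
        h, w = x.shape[-2], x.shape[-1]
        return bilinear_resize(x, h * self.scale, w * self.scale)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def softmax_channels(x: Tensor) -> Tensor:
    """Numerically stable softmax over axis 1 of an (N,C,H,W) tensor."""
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=1, keepdims=True)
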