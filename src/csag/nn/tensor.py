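"""Minimal reverse-mode autodiff over numpy arrays.

Only what the segmentation models need: broadcasting elementwise ops,
matmul, reductions, concatenation/slicing, and a handful of image
primitives (conv2d, pooling, bilinear resize, clipped box sums) with
hand-written adjoints.  Gradients are accumulated in ``Tensor.grad`` by
``Tensor.backward`` after a topological sort of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "bilinear_resize",
    "box_sum",
    "maxpool2x2",
    "avgpool2x2",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind != "f" else self.data.dtype)
        self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def clip_min(self, lo: float):
        """Elementwise max(x, lo); gradient passes where x > lo."""
        mask = self.data > lo

        def backward(g):
            self._accumulate(g * mask)

        return Tensor(np.maximum(self.data, lo), parents=(self,), backward=backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split gradient evenly among ties (ties are measure-zero for floats)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(g * mask / counts)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor(data, parents=(self,), backward=backward)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# image primitives
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, pad: int | None = None) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), 'same' padding by default.

    Computed as k^2 shifted channel matmuls to keep the tape memory at one
    padded copy of the input instead of im2col columns.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    co, ci, k, _ = weight.data.shape
    if pad is None:
        pad = k // 2
    n, c, h, w = x.data.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    ho, wo = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, ho, wo, co), dtype=np.result_type(x.data.dtype, weight.data.dtype))
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + ho, j : j + wo]
            # (N,Ho,Wo,C) @ (C,Co)
            out += np.moveaxis(patch, 1, 3) @ weight.data[:, :, i, j].T
    if bias is not None:
        out += bias.data
    out = np.moveaxis(out, 3, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gm = np.moveaxis(g, 1, 3)  # (N,Ho,Wo,Co)
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            gflat = gm.reshape(-1, co)
            for i in range(k):
                for j in range(k):
                    patch = xp[:, :, i : i + ho, j : j + wo]
                    pf = np.moveaxis(patch, 1, 3).reshape(-1, ci)
                    gw[:, :, i, j] = gflat.T @ pf
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, ci), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + ho, j : j + wo, :] += gm @ weight.data[:, :, i, j]
            x._accumulate(np.moveaxis(dxp[:, pad : pad + h, pad : pad + w, :], 3, 1))

    return Tensor(out, parents=parents, backward=backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch norm over (0,2,3); returns (out, mean, var).

    Stores only x-hat and the inverse std on the tape.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = x.data.var(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)
    m = x.data.size // x.data.shape[1]

    def backward(g):
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        if gamma.requires_grad:
            gamma._accumulate(gxsum.reshape(-1))
        if beta.requires_grad:
            beta._accumulate(gsum.reshape(-1))
        if x.requires_grad:
            gr = gamma.data.reshape(1, -1, 1, 1)
            dx = (gr * inv / m) * (m * g - gsum - xhat * gxsum)
            x._accumulate(dx.astype(x.data.dtype, copy=False))

    return Tensor(out, parents=(x, gamma, beta), backward=backward), mu.reshape(-1), var.reshape(-1)


def maxpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    return Tensor(out, parents=(x,), backward=backward)


def avgpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avgpool2x2 requires even spatial dims")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accumulate(gx)

    return Tensor(out, parents=(x,), backward=backward)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Bilinear interpolation matrix (half-pixel centers, edge-clamped)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize_numpy(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Plain-numpy separable bilinear resize of (..., H, W)."""
    h, w = x.shape[-2], x.shape[-1]
    if (h, w) == (out_h, out_w):
        return x.copy()
    lh = _interp_matrix(out_h, h, np.result_type(x.dtype, np.float64))
    lw = _interp_matrix(out_w, w, np.result_type(x.dtype, np.float64))
    y = np.einsum("Hh,...hw,Ww->...HW", lh, x, lw, optimize=True)
    return y.astype(x.dtype, copy=False)


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    x = as_tensor(x)
    h, w = x.data.shape[-2], x.data.shape[-1]
    dt = x.data.dtype if x.data.dtype.kind == "f" else np.float64
    lh = _interp_matrix(out_h, h, dt)
    lw = _interp_matrix(out_w, w, dt)
    out = np.einsum("Hh,...hw,Ww->...HW", lh, x.data, lw, optimize=True)

    def backward(g):
        gx = np.einsum("Hh,...HW,Ww->...hw", lh, g, lw, optimize=True)
        x._accumulate(gx)

    return Tensor(out, parents=(x,), backward=backward)


def _box_sum_1d(x: np.ndarray, r: int, axis: int) -> np.ndarray:
    n = x.shape[axis]
    c = np.cumsum(x, axis=axis, dtype=np.result_type(x.dtype, np.float64))
    pad_shape = list(x.shape)
    pad_shape[axis] = 1
    c = np.concatenate([np.zeros(pad_shape, dtype=c.dtype), c], axis=axis)
    hi = np.minimum(np.arange(n) + r + 1, n)
    lo = np.maximum(np.arange(n) - r, 0)
    return np.take(c, hi, axis=axis) - np.take(c, lo, axis=axis)


def box_sum_numpy(x: np.ndarray, r: int) -> np.ndarray:
    """Sum of x over border-clipped (2r+1)^2 windows, via running cumsums."""
    y = _box_sum_1d(x, r, x.ndim - 2)
    y = _box_sum_1d(y, r, x.ndim - 1)
    return y.astype(np.result_type(x.dtype, np.float64), copy=False)


def box_sum(x: Tensor, r: int) -> Tensor:
    """Autodiff clipped box sum; the operator is symmetric, so the adjoint
    is the same box sum applied to the upstream gradient."""
    x = as_tensor(x)
    out = box_sum_numpy(x.data, r).astype(x.data.dtype, copy=False)

    def backward(g):
        x._accumulate(box_sum_numpy(g, r).astype(x.data.dtype, copy=False))

    return Tensor(out, parents=(x,), backward=backward)
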