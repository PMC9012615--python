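"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the style of the classic define-by-run
frameworks: every :class:`Tensor` records the operation that produced it
and a closure that propagates the upstream gradient to its parents.
``Tensor.backward()`` topologically sorts the tape and runs the closures
once each.

Only the operations the RA-CNN needs are implemented, but each is exact
(gradients are verified against central finite differences in the test
suite): broadcast arithmetic, matmul, relu/exp/log/sqrt, reductions,
reshape/transpose/slicing/concatenation, im2col/col2im (convolution),
max pooling and bilinear resampling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus, optionally, a gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward, requires_grad) -> "Tensor":
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._prev = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        rg = self.requires_grad or other.requires_grad
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward, rg)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        rg = self.requires_grad or other.requires_grad
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward, rg)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = self._wrap(other)
        rg = self.requires_grad or other.requires_grad
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward, rg)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def sqrt(self):
        return self ** 0.5

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward, self.requires_grad)

    # -- structured ops for convolutional nets ----------------------------------
    def im2col(self, kh: int, kw: int, stride: int, pad: int):
        """Unfold (N, C, H, W) into (N, C*kh*kw, OH*OW) patches."""
        n, c, h, w = self.shape
        oh = (h + 2 * pad - kh) // stride + 1
        ow = (w + 2 * pad - kw) // stride + 1
        x = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        sh = x.strides
        view = np.lib.stride_tricks.as_strided(
            x,
            shape=(n, c, kh, kw, oh, ow),
            strides=(sh[0], sh[1], sh[2], sh[3], sh[2] * stride, sh[3] * stride),
        )
        out_data = view.reshape(n, c * kh * kw, oh * ow).copy()

        def backward(g):
            if not self.requires_grad:
                return
            gcol = g.reshape(n, c, kh, kw, oh, ow)
            gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += gcol[:, :, i, j]
            if pad:
                gx = gx[:, :, pad : pad + h, pad : pad + w]
            self._accum(gx)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def maxpool2d(self, k: int, stride: int, pad: int = 0):
        n, c, h, w = self.shape
        oh = (h + 2 * pad - k) // stride + 1
        ow = (w + 2 * pad - k) // stride + 1
        x = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
        best = np.full((n, c, oh, ow), -np.inf, dtype=np.float32)
        arg = np.zeros((n, c, oh, ow), dtype=np.int8)  # offset index 0..k*k-1
        for i in range(k):
            for j in range(k):
                patch = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
                take = patch > best
                best = np.where(take, patch, best)
                arg = np.where(take, np.int8(i * k + j), arg)

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    mask = arg == (i * k + j)
                    gx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += g * mask
            if pad:
                gx = gx[:, :, pad : pad + h, pad : pad + w]
            self._accum(gx)

        return self._make(best, (self,), backward, self.requires_grad)

    def bilinear_resize(self, out_h: int, out_w: int):
        """Resize the last two axes of (N, C, H, W) with bilinear interpolation.

        Uses the half-pixel-center convention (align_corners=False).
        """
        n, c, h, w = self.shape
        y0, y1, wy = _bilinear_coeffs(h, out_h)
        x0, x1, wx = _bilinear_coeffs(w, out_w)
        d = self.data
        # gather the four neighbours; weights broadcast over (N, C)
        wy0 = (1.0 - wy)[:, None]
        wy1 = wy[:, None]
        wx0 = (1.0 - wx)[None, :]
        wx1 = wx[None, :]
        out_data = (
            d[:, :, y0[:, None], x0[None, :]] * (wy0 * wx0)
            + d[:, :, y0[:, None], x1[None, :]] * (wy0 * wx1)
            + d[:, :, y1[:, None], x0[None, :]] * (wy1 * wx0)
            + d[:, :, y1[:, None], x1[None, :]] * (wy1 * wx1)
        ).astype(np.float32)

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            yy0 = y0[:, None] * w
            yy1 = y1[:, None] * w
            flat = gx.reshape(n, c, h * w)
            for rows, cols, wgt in (
                (yy0, x0[None, :], wy0 * wx0),
                (yy0, x1[None, :], wy0 * wx1),
                (yy1, x0[None, :], wy1 * wx0),
                (yy1, x1[None, :], wy1 * wx1),
            ):
                idx = (rows + cols).ravel()
                np.add.at(flat, (slice(None), slice(None), idx), (g * wgt).reshape(n, c, -1))
            self._accum(flat.reshape(n, c, h, w))

        return self._make(out_data, (self,), backward, self.requires_grad)

    # -- graph execution ---------------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (many layers)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate gradients / tape as we go
                if node is not self:
                    node._backward = None


def _bilinear_coeffs(in_size: int, out_size: int):
    """Source indices and fractional weights for half-pixel-center resampling."""
    pos = (np.arange(out_size, dtype=np.float64) + 0.5) * (in_size / out_size) - 0.5
    pos = np.clip(pos, 0.0, in_size - 1.0)
    lo = np.floor(pos).astype(np.int64)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = (pos - lo).astype(np.float32)
    return lo, hi, frac


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiable."""
    tensors = [Tensor._wrap(t) for t in tensors]
    rg = any(t.requires_grad for t in tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward, rg)
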