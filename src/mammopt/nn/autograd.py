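"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based scalar-loss engine sized for the small convolutional models in
this package: every op builds a node closure that accumulates gradients into
its inputs, and ``Tensor.backward`` walks the graph in reverse topological
order. Arrays are float64 throughout; determinism follows from numpy's.

Only the operations the segmentation and classification networks need are
implemented: broadcast arithmetic, matmul (batched, matching batch dims),
dilated 2-D convolution (stride 1, "same" padding), 2x average pooling,
nearest 2x upsampling, relu/sigmoid/exp/log/pow, softmax, reductions,
reshape/transpose/concat, and fused numerically-stable losses. Gradients
are exercised against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # ---- graph plumbing -------------------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    # ---- arithmetic -----------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_sum_to(g, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._node(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_sum_to(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_sum_to(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._node(a.data / b.data, (a, b), back)

    def __pow__(self, p: float):
        a = self

        def back(g):
            if a.requires_grad:
                a._accum(g * p * np.power(a.data, p - 1.0))

        return Tensor._node(np.power(a.data, p), (a,), back)

    # ---- nonlinearities -------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def back(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._node(a.data * mask, (a,), back)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def back(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._node(s, (a,), back)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def back(g):
            if a.requires_grad:
                a._accum(g * e)

        return Tensor._node(e, (a,), back)

    def log(self):
        a = self

        def back(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._node(np.log(a.data), (a,), back)

    # ---- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )

        def back(g):
            if not a.requires_grad:
                return
            gg = np.asarray(g) / n
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(a.data.mean(axis=axis, keepdims=keepdims), (a,), back)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def back(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._node(a.data.reshape(*shape), (a,), back)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def back(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._node(a.data.transpose(axes), (a,), back)

    @staticmethod
    def concat(tensors, axis: int = 1):
        parts = [Tensor._wrap(t) for t in tensors]
        sizes = [p.data.shape[axis] for p in parts]
        offs = np.cumsum([0] + sizes)

        def back(g):
            for p, lo, hi in zip(parts, offs[:-1], offs[1:]):
                if p.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    p._accum(g[tuple(idx)])

        return Tensor._node(
            np.concatenate([p.data for p in parts], axis=axis), parts, back
        )

    # ---- linear algebra --------------------------------------------------
    def matmul(self, other):
        a, b = self, Tensor._wrap(other)

        def back(g):
            if a.requires_grad:
                a._accum(_sum_to(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape))

        return Tensor._node(np.matmul(a.data, b.data), (a, b), back)

    __matmul__ = matmul

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            if a.requires_grad:
                a._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor._node(s, (a,), back)

    # ---- convolution & spatial ops ---------------------------------------
    def conv2d(self, w: "Tensor", b: "Tensor | None" = None, dilation: int = 1):
        """Stride-1 'same' 2-D convolution with dilation.

        self: (N, C, H, W); w: (Cout, C, kh, kw); b: (Cout,).
        """
        a = self
        N, C, H, W = a.data.shape
        Co, Ci, kh, kw = w.data.shape
        if Ci != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
        d = int(dilation)
        ph, pw = d * (kh // 2), d * (kw // 2)
        xp = np.pad(a.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = np.empty((kh, kw, N, C, H, W))
        for i in range(kh):
            for j in range(kw):
                cols[i, j] = xp[:, :, i * d : i * d + H, j * d : j * d + W]
        colm = cols.transpose(2, 4, 5, 3, 0, 1).reshape(N * H * W, C * kh * kw)
        wm = w.data.reshape(Co, C * kh * kw)
        out = (colm @ wm.T).reshape(N, H, W, Co).transpose(0, 3, 1, 2)
        if b is not None:
            out = out + b.data.reshape(1, Co, 1, 1)
        parents = (a, w) if b is None else (a, w, b)

        def back(g):
            gm = g.transpose(0, 2, 3, 1).reshape(N * H * W, Co)
            if w.requires_grad:
                w._accum((gm.T @ colm).reshape(Co, C, kh, kw))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                dcol = (gm @ wm).reshape(N, H, W, C, kh, kw).transpose(4, 5, 0, 3, 1, 2)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i * d : i * d + H, j * d : j * d + W] += dcol[i, j]
                a._accum(dxp[:, :, ph : ph + H, pw : pw + W] if ph or pw else dxp)

        return Tensor._node(out, parents, back)

    def avg_pool2(self):
        """2x2 average pooling, stride 2. Spatial dims must be even."""
        a = self
        N, C, H, W = a.data.shape
        out = a.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

        def back(g):
            if a.requires_grad:
                gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
                a._accum(gg)

        return Tensor._node(out, (a,), back)

    def upsample2(self):
        """Nearest-neighbour 2x spatial upsampling."""
        a = self
        N, C, H, W = a.data.shape
        out = np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3)

        def back(g):
            if a.requires_grad:
                a._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return Tensor._node(out, (a,), back)

    # ---- fused losses -----------------------------------------------------
    def bce_with_logits(self, target: np.ndarray):
        """Mean binary cross-entropy on logits (numerically stable)."""
        a = self
        t = np.asarray(target, dtype=np.float64)
        z = a.data
        loss = np.maximum(z, 0) - t * z + np.log1p(np.exp(-np.abs(z)))
        n = z.size

        def back(g):
            if a.requires_grad:
                s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
                a._accum(g * (s - t) / n)

        return Tensor._node(loss.mean(), (a,), back)

    def softmax_cross_entropy(self, labels: np.ndarray):
        """Mean cross-entropy of (N, K) logits against integer labels."""
        a = self
        labels = np.asarray(labels, dtype=np.int64)
        z = a.data - a.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        n = z.shape[0]
        loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))

        def back(g):
            if a.requires_grad:
                d = p.copy()
                d[np.arange(n), labels] -= 1.0
                a._accum(g * d / n)

        return Tensor._node(loss, (a,), back)
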