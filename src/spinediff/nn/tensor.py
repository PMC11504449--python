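"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: each :class:`Tensor` wraps a ``float32`` ndarray
and remembers how it was produced.  ``Tensor.backward()`` topologically sorts
the tape and accumulates gradients into ``.grad``.  Only the operations the
segmentation networks need are implemented (elementwise arithmetic with
broadcasting, matmul, reductions, shape surgery, 2-D convolution with
dilation/groups, pooling and the activations).  Everything is CPU NumPy;
determinism follows from seeding the NumPy generators that feed the graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d", "upsample_nearest2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager suppressing tape construction (inference-time speed)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = (requires_grad or any(p.requires_grad for p in parents)) \
            and _GRAD_ENABLED[0]
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (per-timestep chains)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.ndim for a in ax))
            self._accum(np.broadcast_to(g, self.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == y)
        # ties share the gradient equally
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out = Tensor(y if keepdims else y.squeeze(axis), parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask)

        out._backward = bwd
        return out

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bwd
        return out

    # ------------------------------------------------------------ activations
    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 + self.data * (1.0 - s)))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def elu(self):
        neg = self.data <= 0
        e = np.exp(np.minimum(self.data, 0.0))
        y = np.where(neg, e - 1.0, self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(neg, e, 1.0))
        return out

    def clamp(self, lo: float, hi: float):
        """Hard clamp; gradient is zero outside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = lambda g: self._accum(g * inside)
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accum(g[tuple(sl)])
            start += s

    out._backward = bwd
    return out


# ---------------------------------------------------------------- convolution
def _im2col(xp: np.ndarray, kh: int, kw: int, dh: int, dw: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * dh:i * dh + ho, j * dw:j * dw + wo]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (C_out, C_in/groups, kh, kw).  Depthwise = groups == C_in.
    """
    x = Tensor._lift(x)
    n, cin, h, wd = x.shape
    cout, cpg, kh, kw = w.shape
    assert cin == cpg * groups, "channel/group mismatch"
    dh = dw = dilation
    ho = h + 2 * padding - dilation * (kh - 1)
    wo = wd + 2 * padding - dilation * (kw - 1)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data

    if groups == cin and cpg == 1 and cout == cin:
        return _depthwise(x, xp, w, b, padding, dh, dw, ho, wo, h, wd)

    cols = _im2col(xp, kh, kw, dh, dw, ho, wo)

    if groups == 1:
        cols2 = cols.reshape(n, cin * kh * kw, ho * wo)
        w2 = w.data.reshape(cout, cin * kh * kw)
        y = np.matmul(w2[None], cols2).reshape(n, cout, ho, wo)
    else:
        colsg = cols.reshape(n, groups, cpg, kh, kw, ho, wo)
        wg = w.data.reshape(groups, cout // groups, cpg, kh, kw)
        y = np.einsum("ngcijhw,gocij->ngohw", colsg, wg, optimize=True)
        y = y.reshape(n, cout, ho, wo)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bwd(g):
        g = np.ascontiguousarray(g)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            g2 = g.reshape(n, cout, ho * wo)
            if w.requires_grad:
                cols2b = cols.reshape(n, cin * kh * kw, ho * wo)
                dw_ = np.matmul(g2, cols2b.transpose(0, 2, 1)).sum(axis=0)
                w._accum(dw_.reshape(w.shape))
            if x.requires_grad:
                w2b = w.data.reshape(cout, cin * kh * kw)
                dcols = np.matmul(w2b.T[None], g2).reshape(n, cin, kh, kw, ho, wo)
                x._accum(_col2im(dcols, xp.shape, padding, dh, dw, h, wd))
        else:
            colsg = cols.reshape(n, groups, cpg, kh, kw, ho, wo)
            gg = g.reshape(n, groups, cout // groups, ho, wo)
            if w.requires_grad:
                dw_ = np.einsum("ngohw,ngcijhw->gocij", gg, colsg, optimize=True)
                w._accum(dw_.reshape(w.shape))
            if x.requires_grad:
                wg = w.data.reshape(groups, cout // groups, cpg, kh, kw)
                dcols = np.einsum("ngohw,gocij->ngcijhw", gg, wg, optimize=True)
                dcols = dcols.reshape(n, cin, kh, kw, ho, wo)
                x._accum(_col2im(dcols, xp.shape, padding, dh, dw, h, wd))

    out._backward = bwd
    return out


def _depthwise(x: Tensor, xp: np.ndarray, w: Tensor, b: Tensor | None,
               padding: int, dh: int, dw: int, ho: int, wo: int,
               h: int, wd: int) -> Tensor:
    """Depthwise convolution via fused slice multiply-adds (no im2col buffer)."""
    n, c, _, _ = xp.shape
    _, _, kh, kw = w.shape
    wv = w.data[:, 0]  # (C, kh, kw)
    y = np.zeros((n, c, ho, wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            y += wv[:, i, j][None, :, None, None] * \
                xp[:, :, i * dh:i * dh + ho, j * dw:j * dw + wo]
    if b is not None:
        y += b.data.reshape(1, c, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw_ = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i * dh:i * dh + ho, j * dw:j * dw + wo]
                    dw_[:, 0, i, j] = np.einsum("nchw,nchw->c", g, patch)
            w._accum(dw_)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dh:i * dh + ho, j * dw:j * dw + wo] += \
                        wv[:, i, j][None, :, None, None] * g
            if padding:
                x._accum(dxp[:, :, padding:padding + h, padding:padding + wd])
            else:
                x._accum(dxp)

    out._backward = bwd
    return out


def _col2im(dcols: np.ndarray, padded_shape, padding: int, dh: int, dw: int,
            h: int, w: int) -> np.ndarray:
    n, c, kh, kw, ho, wo = dcols.shape
    dx = np.zeros(padded_shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i * dh:i * dh + ho, j * dw:j * dw + wo] += dcols[:, :, i, j]
    if padding:
        dx = dx[:, :, padding:padding + h, padding:padding + w]
    return dx


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling; H and W must be divisible by k."""
    n, c, h, w = x.shape
    assert h % k == 0 and w % k == 0, "avg_pool2d needs divisible spatial dims"
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = Tensor(y, parents=(x,))

    def bwd(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gg)

    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out
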