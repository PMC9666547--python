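"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine supports exactly the operations the distogram network needs:
broadcast arithmetic, matmul, same-padding 2D convolution (via im2col),
axis reductions (sum/mean/max), elementwise nonlinearities, reshape /
concatenate, and a fused masked softmax cross-entropy. Tensors hold
float32 data; gradients are accumulated into ``.grad`` by ``backward()``
over a topologically sorted graph.

Graph recording can be suspended with the ``no_grad()`` context manager,
which makes inference allocation-free apart from the forward activations.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), bwd)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(self.data) - 1.0))

        def bwd(g):
            self._accum(g * np.where(pos, 1.0, out_data + alpha))

        return self._make(out_data.astype(np.float32), (self,), bwd)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        mask = self.data == m
        counts = mask.sum(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask / counts)

        return self._make(out_data, (self,), bwd)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    ref = tensors[0]
    return ref._make(out_data, tuple(tensors), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 2D convolution.

    ``x`` is (H, W, Cin), ``w`` is (kh, kw, Cin, Cout), ``b`` is (Cout,).
    Implemented with im2col so the heavy lifting is one GEMM each way.
    """
    H, W, cin = x.data.shape
    kh, kw, cin_w, cout = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((ph, ph), (pw, pw), (0, 0)))
    # (H, W, kh, kw, Cin) view -> (H*W, kh*kw*Cin)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(0, 1))
    col = np.ascontiguousarray(win.transpose(0, 1, 3, 4, 2)).reshape(H * W, -1)
    wm = w.data.reshape(-1, cout)
    out_data = (col @ wm + b.data).reshape(H, W, cout)

    def bwd(g):
        gm = g.reshape(H * W, cout)
        if w.requires_grad:
            w._accum((col.T @ gm).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            gcol = (gm @ wm.T).reshape(H, W, kh, kw, cin)
            gxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    gxp[di : di + H, dj : dj + W] += gcol[:, :, di, dj]
            x._accum(gxp[ph : ph + H, pw : pw + W])

    return x._make(out_data, (x, w, b), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return x._make(s, (x,), bwd)


def masked_softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, mask: np.ndarray
) -> Tensor:
    """Mean of -log softmax(logits)[label] over cells where ``mask`` is true.

    ``logits`` is (H, W, B); ``labels`` is (H, W) integer bins; ``mask``
    (H, W) boolean. Fused for numerical stability: the backward pass is
    (softmax - onehot) * mask / n_masked, so unmasked cells contribute
    exactly zero gradient.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty loss support")
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    ii, jj = np.nonzero(mask)
    picked = logp[ii, jj, labels[ii, jj]]
    loss = -picked.mean()

    def bwd(g):
        p = np.exp(logp)
        grad = p.copy()
        grad[ii, jj, labels[ii, jj]] -= 1.0
        grad *= mask[:, :, None] / n
        logits._accum(g * grad)

    return logits._make(np.float32(loss), (logits,), bwd)
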