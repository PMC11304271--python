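"""Minimal reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation over the recorded
graph.  Only the operations needed by the conditional-GAN backbone and the
distillation classifiers are provided (dense/conv/transposed-conv algebra,
pointwise nonlinearities, reductions, fused stable losses).  Everything is
float32 and CPU-only by design.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "mse_loss",
    "sigmoid_bce_with_logits",
    "softmax_cross_entropy",
]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(-g, other.shape))

        return self._make(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape) / n)

        return self._make(
            self.data.mean(axis=axis, keepdims=keepdims), (self,), bw
        )

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), bw
        )

    # -- pointwise nonlinearities -----------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        mask = self.data > 0
        scale = np.where(mask, 1.0, alpha).astype(np.float32)

        def bw(g):
            self._accum(g * scale)

        return self._make(self.data * scale, (self,), bw)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), bw)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / np.maximum(r, 1e-12))

        return self._make(r, (self,), bw)

    # -- convolution family ------------------------------------------------
    def conv2d(self, w: "Tensor", b: "Tensor", stride: int, pad: int) -> "Tensor":
        x = self.data
        cols, out_hw = _im2col(x, w.shape[2], w.shape[3], stride, pad)
        n = x.shape[0]
        o = w.shape[0]
        wm = w.data.reshape(o, -1)
        y = (wm @ cols).reshape(n, o, *out_hw) + b.data.reshape(1, o, 1, 1)

        def bw(g):
            gm = g.reshape(n, o, -1)
            w._accum(
                np.einsum("nol,nkl->ok", gm, cols).reshape(w.shape)
            )
            b._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.einsum("ok,nol->nkl", wm, gm)
                self._accum(
                    _col2im(dcols, x.shape, w.shape[2], w.shape[3], stride, pad)
                )

        return self._make(y, (self, w, b), bw)

    def conv_transpose2d(
        self, w: "Tensor", b: "Tensor", stride: int, pad: int
    ) -> "Tensor":
        # weight layout (C_in, C_out, kh, kw); forward is the input-gradient
        # of the corresponding stride-`stride` convolution
        x = self.data
        n, cin, h, ww_ = x.shape
        _, cout, kh, kw = w.shape
        oh = (h - 1) * stride - 2 * pad + kh
        ow = (ww_ - 1) * stride - 2 * pad + kw
        wm = w.data.reshape(cin, -1)  # (cin, cout*kh*kw)
        xm = x.reshape(n, cin, -1)
        dcols = np.einsum("ck,ncl->nkl", wm, xm)
        y = _col2im(dcols, (n, cout, oh, ow), kh, kw, stride, pad)
        y = y + b.data.reshape(1, cout, 1, 1)

        def bw(g):
            cols_g, _ = _im2col(g, kh, kw, stride, pad)
            b._accum(g.sum(axis=(0, 2, 3)))
            w._accum(
                np.einsum("ncl,nkl->ck", xm, cols_g).reshape(w.shape)
            )
            if self.requires_grad:
                dx = np.einsum("ck,nkl->ncl", wm, cols_g).reshape(x.shape)
                self._accum(dx)

        return self._make(y, (self, w, b), bw)

    def maxpool2(self) -> "Tensor":
        """2x2 max pooling, stride 2 (even spatial dims required)."""
        n, c, h, w = self.shape
        h2, w2 = h // 2, w // 2
        # window-major layout (n,c,h2,w2,4)
        xw = (
            self.data.reshape(n, c, h2, 2, w2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2, w2, 4)
        )
        y = xw.max(axis=-1)
        mask = xw == y[..., None]
        # break ties toward a single winner to keep gradients well-scaled
        cum = np.cumsum(mask, axis=-1)
        first = (cum == 1) & mask

        def bw(g):
            gw = g[..., None] * first
            gx = (
                gw.reshape(n, c, h2, w2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h, w)
            )
            self._accum(gx.astype(np.float32))

        return self._make(y, (self,), bw)


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n,c,oh,ow,kh,kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(cols, xshape, kh, kw, stride, pad):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, c, hp, wp), dtype=np.float32)
    cr = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cr[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gp in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gp)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


# -- fused losses ----------------------------------------------------------
def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    t = target.data if isinstance(target, Tensor) else _as_array(target)
    diff = pred.data - t
    n = diff.size

    def bw(g):
        pred._accum(g * 2.0 * diff / n)

    return pred._make(np.float32((diff**2).mean()), (pred,), bw)


def sigmoid_bce_with_logits(logits: Tensor, target: float | np.ndarray) -> Tensor:
    z = logits.data
    t = np.broadcast_to(_as_array(target), z.shape)
    # stable: max(z,0) - z t + log1p(exp(-|z|))
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * (s - t) / n)

    return logits._make(np.float32(loss.mean()), (logits,), bw)


def softmax_cross_entropy(logits: Tensor, target_probs: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against target distributions.

    ``target_probs`` may be one-hot rows (supervised CE) or uniform rows
    (confusion objective used for batch-information removal).
    """
    z = logits.data
    t = _as_array(target_probs)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    loss = (t * (lse - z)).sum(axis=1).mean()
    n = z.shape[0]

    def bw(g):
        p = np.exp(z - lse)
        logits._accum(g * (p - t) / n)

    return logits._make(np.float32(loss), (logits,), bw)


def softmax(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=1, keepdims=True)
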