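"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations needed by the planar U-Nets and the
adaptation heads: elementwise arithmetic, matmul, 2D convolution
(stride 1, 'same' or 'valid' padding), 2x2 max-pooling, bilinear
resizing, batch normalisation, dropout, channel softmax and the
gradient-reversal operation. Arrays keep whatever float dtype they are
given (float32 for training, float64 for finite-difference checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "resize_bilinear",
    "batch_norm",
    "dropout",
    "softmax",
    "log_softmax",
    "gather_channel",
    "grad_reverse",
    "relu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), grad_fn=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._grad_fn = grad_fn

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            parent_grads = node._grad_fn(node.grad)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
            grad_fn=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(
            -self.data,
            requires_grad=self.requires_grad,
            parents=(self,),
            grad_fn=lambda g: (-g,),
        )

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
            grad_fn=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
            grad_fn=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape),
            ),
        )
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(
            self.data ** exponent,
            requires_grad=self.requires_grad,
            parents=(self,),
            grad_fn=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
            grad_fn=lambda g: (g @ other.data.T, self.data.T @ g),
        )
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gx = g
            if not keepdims:
                gx = np.expand_dims(gx, axis)
            return (np.broadcast_to(gx, self.shape).copy(),)

        return Tensor(data, self.requires_grad, (self,), grad_fn)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(
            self.data.reshape(shape),
            self.requires_grad,
            (self,),
            lambda g: (g.reshape(self.shape),),
        )
        return out

    def flatten_batch(self):
        """Reshape (N, ...) -> (N, prod(...))."""
        n = self.shape[0]
        return self.reshape(n, -1)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask,
            self.requires_grad,
            (self,),
            lambda g: (g * mask,),
        )

    def log(self):
        return Tensor(
            np.log(self.data),
            self.requires_grad,
            (self,),
            lambda g: (g / self.data,),
        )

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, self.requires_grad, (self,), lambda g: (g * out_data,))

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        return Tensor(
            np.maximum(self.data, lo),
            self.requires_grad,
            (self,),
            lambda g: (g * mask,),
        )


def relu(x: Tensor) -> Tensor:
    return x.relu()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors), grad_fn)


# -- convolution -------------------------------------------------------------

def _conv_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation. x (N,C,H,W), w (O,C,kh,kw) -> (N,O,H',W')."""
    kh, kw = w.shape[2], w.shape[3]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,H',W',kh,kw
    out = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # N,H',W',O
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """2D convolution, stride 1. Padding must give kh-1-padding >= 0."""
    out_data = _conv_raw(x.data, w.data, padding)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    kh, kw = w.shape[2], w.shape[3]

    def grad_fn(g):
        gx = gw = gb = None
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx = _conv_raw(g, np.ascontiguousarray(w_flip), kh - 1 - padding)
        if w.requires_grad:
            xp = x.data
            if padding:
                xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
            cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
            # (N,C,H',W',kh,kw) x (N,O,H',W') -> (C,kh,kw,O)
            gw = np.tensordot(cols, g, axes=([0, 2, 3], [0, 2, 3]))
            gw = gw.transpose(3, 0, 1, 2)
        if b is not None and b.requires_grad:
            gb = g.sum(axis=(0, 2, 3))
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    req = any(p.requires_grad for p in parents)
    return Tensor(out_data, req, parents, grad_fn)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k; trailing rows/cols are dropped (floor)."""
    n, c, h, w = x.shape
    h2, w2 = h // k, w // k
    xc = x.data[:, :, : h2 * k, : w2 * k]
    windows = xc.reshape(n, c, h2, k, w2, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, k * k)
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gwin = np.zeros((n, c, h2, w2, k * k), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : h2 * k, : w2 * k] = (
            gwin.reshape(n, c, h2, w2, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * k, w2 * k)
        )
        return (gx,)

    return Tensor(out_data, x.requires_grad, (x,), grad_fn)


def _interp_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix (n_out x n_in), pixel-centre aligned."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    centres = (np.arange(n_out) + 0.5) * scale - 0.5
    centres = np.clip(centres, 0, n_in - 1)
    i0 = np.floor(centres).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = centres - i0
    np.add.at(m, (np.arange(n_out), i0), 1 - t)
    np.add.at(m, (np.arange(n_out), i1), t)
    return m


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N,C,H,W) to (N,C,h,w) as two 1-D interpolations."""
    h_out, w_out = out_hw
    _, _, h, w = x.shape
    ah = _interp_matrix(h, h_out, x.dtype)
    aw = _interp_matrix(w, w_out, x.dtype)
    tmp = np.tensordot(x.data, ah, axes=([2], [1]))  # N,C,W,h
    out_data = np.tensordot(tmp, aw, axes=([2], [1]))  # N,C,h,w
    out_data = np.ascontiguousarray(out_data)

    def grad_fn(g):
        t = np.tensordot(g, ah, axes=([2], [0]))  # N,C,w,H
        gx = np.tensordot(t, aw, axes=([2], [0]))  # N,C,H,W
        return (np.ascontiguousarray(gx),)

    return Tensor(out_data, x.requires_grad, (x,), grad_fn)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N,H,W) per channel. Mutates running stats in training."""
    g4 = gamma.data.reshape(1, -1, 1, 1)
    b4 = beta.data.reshape(1, -1, 1, 1)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out_data = g4 * xhat + b4
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def grad_fn(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3)) if gamma.requires_grad else None
        gbeta = g.sum(axis=(0, 2, 3)) if beta.requires_grad else None
        gx = None
        if x.requires_grad:
            scale = g4 * inv_std.reshape(1, -1, 1, 1)
            if training:
                gmean = g.mean(axis=(0, 2, 3), keepdims=True)
                gxhat_mean = (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                gx = scale * (g - gmean - xhat * gxhat_mean)
            else:
                gx = scale * g
        return (gx, ggamma, gbeta)

    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    return Tensor(out_data, req, (x, gamma, beta), grad_fn)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    return Tensor(x.data * mask, x.requires_grad, (x,), lambda g: (g * mask,))


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return Tensor(p, x.requires_grad, (x,), grad_fn)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    logp = z - lse
    p = np.exp(logp)

    def grad_fn(g):
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor(logp, x.requires_grad, (x,), grad_fn)


def gather_channel(p: Tensor, index: np.ndarray) -> Tensor:
    """Select p[n, index[n,h,w], h, w] from a (N,C,H,W) tensor -> (N,H,W)."""
    idx = index.astype(np.int64)
    out_data = np.take_along_axis(p.data, idx[:, None, :, :], axis=1)[:, 0]

    def grad_fn(g):
        gp = np.zeros_like(p.data)
        np.put_along_axis(gp, idx[:, None, :, :], g[:, None, :, :], axis=1)
        return (gp,)

    return Tensor(out_data, p.requires_grad, (p,), grad_fn)


def grad_reverse(x: Tensor, lam: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the backward gradient by -lam."""
    if lam < 0:
        raise ValueError("gradient-reversal scale must be >= 0")
    return Tensor(x.data, x.requires_grad, (x,), lambda g: (-lam * g,))
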