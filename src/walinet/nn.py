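"""Minimal neural-network engine on numpy.

Reverse-mode automatic differentiation over the handful of operations
the Y-Net needs: 1-D same-padded convolutions (im2col + BLAS matmul),
PReLU, dropout, max-pooling, linear upsampling, channel concatenation
and mean-squared error.  Arrays are float32 by default; the engine is
dtype-agnostic so gradient checks can run in float64.

This is deliberately small: no broadcasting rules beyond what the
network uses, no graphs retained across steps, explicit parameter
objects, and a standard Adam optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv1d",
    "prelu",
    "dropout",
    "maxpool2",
    "upsample_linear2",
    "upsample_nearest2",
    "concat",
    "pad_right",
    "crop_right",
    "add",
    "mse_loss",
    "Adam",
]


class Tensor:
    """Array node of the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


class Parameter(Tensor):
    """Trainable tensor with Adam state attached lazily."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data), requires_grad=True)


def _node(data, parents, backward, requires_grad=None) -> Tensor:
    out = Tensor(data)
    out.requires_grad = (
        any(p.requires_grad for p in parents) if requires_grad is None else requires_grad
    )
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def conv1d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation).

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, k) with odd k; ``b``: (C_out,).
    """
    xb, wd = x.data, w.data
    batch, cin, length = xb.shape
    cout, cin_w, k = wd.shape
    assert cin == cin_w and k % 2 == 1
    p = k // 2
    xp = np.zeros((batch, cin, length + 2 * p), dtype=xb.dtype)
    xp[:, :, p : p + length] = xb
    # (B, C, L, k) windows -> (B*L, C*k) patch matrix
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    cols = win.transpose(0, 2, 1, 3).reshape(batch * length, cin * k)
    out = cols @ wd.reshape(cout, cin * k).T + b.data
    out = out.reshape(batch, length, cout).transpose(0, 2, 1)

    def backward(g: np.ndarray) -> None:
        gm = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(batch * length, cout)
        if w.requires_grad:
            w._accumulate((gm.T @ cols).reshape(cout, cin, k))
        if b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wd.reshape(cout, cin * k)).reshape(batch, length, cin, k)
            dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, L, k)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + length] += dcols[:, :, :, j]
            x._accumulate(dxp[:, :, p : p + length])

    return _node(out, (x, w, b), backward)


def prelu(x: Tensor, a: Parameter) -> Tensor:
    """Per-channel parametric ReLU; ``a``: (C,) slopes for x < 0."""
    xb = x.data
    neg = xb < 0
    slope = a.data.reshape(1, -1, 1)
    out = np.where(neg, slope * xb, xb)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate((np.where(neg, xb, 0.0) * g).sum(axis=(0, 2)))
        if x.requires_grad:
            x._accumulate(np.where(neg, slope * g, g))

    return _node(out, (x, a), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    return _node(out, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    """Max pooling with kernel and stride 2 along the last axis."""
    xb = x.data
    batch, c, length = xb.shape
    assert length % 2 == 0
    pairs = xb.reshape(batch, c, length // 2, 2)
    idx = pairs.argmax(axis=3)
    out = np.take_along_axis(pairs, idx[..., None], axis=3)[..., 0]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dp = np.zeros_like(pairs)
            np.put_along_axis(dp, idx[..., None], g[..., None], axis=3)
            x._accumulate(dp.reshape(batch, c, length))

    return _node(out, (x,), backward)


def upsample_linear2(x: Tensor) -> Tensor:
    """Double the last axis by linear interpolation (edge clamped)."""
    xb = x.data
    batch, c, length = xb.shape
    out = np.empty((batch, c, 2 * length), dtype=xb.dtype)
    out[:, :, 0::2] = xb
    out[:, :, 1:-1:2] = 0.5 * (xb[:, :, :-1] + xb[:, :, 1:])
    out[:, :, -1] = xb[:, :, -1]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dx = g[:, :, 0::2].copy()
            mid = g[:, :, 1:-1:2]
            dx[:, :, :-1] += 0.5 * mid
            dx[:, :, 1:] += 0.5 * mid
            dx[:, :, -1] += g[:, :, -1]
            x._accumulate(dx)

    return _node(out, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    xb = x.data
    out = np.repeat(xb, 2, axis=2)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g[:, :, 0::2] + g[:, :, 1::2])

    return _node(out, (x,), backward)


def concat(parts: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis (axis 1)."""
    out = np.concatenate([p.data for p in parts], axis=1)
    sizes = [p.data.shape[1] for p in parts]
    bounds = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for p, lo, hi in zip(parts, bounds[:-1], bounds[1:]):
            if p.requires_grad:
                p._accumulate(g[:, lo:hi])

    return _node(out, tuple(parts), backward)


def pad_right(x: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return x
    xb = x.data
    out = np.concatenate(
        [xb, np.zeros(xb.shape[:2] + (pad,), dtype=xb.dtype)], axis=2
    )

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g[:, :, : xb.shape[2]])

    return _node(out, (x,), backward)


def crop_right(x: Tensor, length: int) -> Tensor:
    if x.data.shape[2] == length:
        return x
    xb = x.data

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dx = np.zeros_like(xb)
            dx[:, :, :length] = g
            x._accumulate(dx)

    return _node(xb[:, :, :length], (x,), backward)


def add(x: Tensor, y: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g)
        if y.requires_grad:
            y._accumulate(g)

    return _node(x.data + y.data, (x, y), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out = np.array(np.mean(diff**2), dtype=pred.data.dtype)

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate((2.0 / diff.size) * diff * g)

    return _node(out, (pred,), backward)


# ----------------------------------------------------------------------
# optimizer
# ----------------------------------------------------------------------

class Adam:
    """Adam with decoupled learning-rate schedule handled by the caller."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
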