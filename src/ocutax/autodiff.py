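"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-free, graph-walking autograd in the micrograd style: every operation
returns a :class:`Tensor` holding its value, its parents and a closure that
pushes the output gradient to the parents.  ``Tensor.backward`` topologically
sorts the graph and accumulates gradients on every node, so intermediate
activations (needed e.g. by Grad-CAM) receive gradients too, not only leaf
parameters.

The op set is exactly what the hierarchical classifier needs: strided 2-D
convolution (via im2col), dense layers, ReLU, sigmoid, global average
pooling, feature concatenation, and the focal loss.  Dtype follows the input
arrays; training code uses float32, gradient-check tests float64.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from . import losses as _losses

__all__ = ["Tensor", "Adam", "conv2d", "dense", "relu", "sigmoid",
           "global_avg_pool", "concat", "focal_loss", "weighted_sum"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self.parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients on every node reachable from this one."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
        self.grad = self.grad + np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"


def parameter(data, rng: np.random.Generator | None = None, name: str = "") -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True, name=name)


# ---------------------------------------------------------------------------
# ops

def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)

    def backward(g: np.ndarray) -> None:
        x.grad += g * (x.data > 0)

    return Tensor(out_data, parents=(x,), backward=backward, name="relu")


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g: np.ndarray) -> None:
        x.grad += g * s * (1.0 - s)

    return Tensor(s, parents=(x,), backward=backward, name="sigmoid")


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map  x @ w + b  for x of shape (n, d_in), w (d_in, d_out)."""
    out_data = x.data @ w.data + b.data

    def backward(g: np.ndarray) -> None:
        x.grad += g @ w.data.T
        w.grad += x.data.T @ g
        b.grad += g.sum(axis=0)

    return Tensor(out_data, parents=(x, w, b), backward=backward, name="dense")


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, via im2col.

    x: (N, C, H, W); w: (C_out, C, K, K); b: (C_out,).
    """
    n, c, h, width = x.data.shape
    c_out, c_in, k, k2 = w.data.shape
    assert c_in == c and k == k2
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, K, K)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    wmat = w.data.reshape(c_out, c * k * k)
    out = cols @ wmat.T + b.data
    out_data = out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)

    need_dx = x.requires_grad or bool(x.parents)

    def backward(g: np.ndarray) -> None:
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
        w.grad += (gmat.T @ cols).reshape(w.data.shape)
        b.grad += gmat.sum(axis=0)
        if not need_dx:  # raw input images: skip the costly col2im scatter
            return
        dcols = gmat @ wmat  # (N*Ho*Wo, C*K*K)
        dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dwin[
                    :, :, :, :, i, j
                ]
        if padding:
            x.grad += dxp[:, :, padding:-padding, padding:-padding]
        else:
            x.grad += dxp

    return Tensor(out_data, parents=(x, w, b), backward=backward, name="conv2d")


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial grid: (N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g: np.ndarray) -> None:
        x.grad += g[:, :, None, None] / (h * w) * np.ones_like(x.data)

    return Tensor(out_data, parents=(x,), backward=backward, name="gap")


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Feature concatenation along axis 1 (the channel/feature axis)."""
    out_data = np.concatenate([a.data, b.data], axis=1)
    na = a.data.shape[1]

    def backward(g: np.ndarray) -> None:
        a.grad += g[:, :na]
        b.grad += g[:, na:]

    return Tensor(out_data, parents=(a, b), backward=backward, name="concat")


def focal_loss(probs: Tensor, labels: np.ndarray, params: "_losses.FocalParams") -> Tensor:
    """Mean focal loss over all cells, differentiable w.r.t. the probabilities.

    Forward and gradient both delegate to :mod:`ocutax.losses` so the training
    objective and the reference NumPy implementation cannot diverge.
    """
    labels = np.asarray(labels)
    value = _losses.level_loss(probs.data, labels, params)

    def backward(g: np.ndarray) -> None:
        probs.grad += float(g) * _losses.level_loss_grad(probs.data, labels, params).astype(
            probs.data.dtype
        )

    return Tensor(
        np.asarray(value, dtype=probs.data.dtype),
        parents=(probs,),
        backward=backward,
        name="focal_loss",
    )


def weighted_sum(terms: Sequence[Tensor], weights: Sequence[float]) -> Tensor:
    """Scalar convex combination  sum_i w_i * t_i  (the total loss)."""
    if len(terms) != len(weights):
        raise ValueError("terms and weights length mismatch")
    out_data = sum(w * t.data for w, t in zip(weights, terms))

    def backward(g: np.ndarray) -> None:
        for w, t in zip(weights, terms):
            t.grad += g * np.asarray(w, dtype=t.data.dtype)

    return Tensor(out_data, parents=tuple(terms), backward=backward, name="total")


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam over an explicit parameter list; supports freezing via the list."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
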