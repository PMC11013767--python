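"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the frequency network needs are provided: dense matmul,
1-D convolution (via im2col), broadcasting add/mul, elementwise relu /
sigmoid / sqrt / square, reductions, and slicing. Gradients are accumulated
by topological-order backprop, numpy-only and deterministic. Gradient
correctness is verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "SGD"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` back to ``shape``."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ ops
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bk(g):
            return (_sum_to_shape(g, self.data.shape),
                    _sum_to_shape(g, other.data.shape))
        out._backward = bk
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bk(g):
            return (_sum_to_shape(g * other.data, self.data.shape),
                    _sum_to_shape(g * self.data, other.data.shape))
        out._backward = bk
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bk(g):
            return (g @ other.data.T, self.data.T @ g)
        out._backward = bk
        return out

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        mask = self.data > 0
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def square(self) -> "Tensor":
        out = Tensor(self.data ** 2, _parents=(self,))
        out._backward = lambda g: (2.0 * g * self.data,)
        return out

    def sqrt(self, eps: float = 0.0) -> "Tensor":
        root = np.sqrt(self.data + eps)
        out = Tensor(root, _parents=(self,))
        out._backward = lambda g: (g * 0.5 / np.maximum(root, 1e-12),)
        return out

    def reciprocal(self, eps: float = 1e-12) -> "Tensor":
        inv = 1.0 / (self.data + eps)
        out = Tensor(inv, _parents=(self,))
        out._backward = lambda g: (-g * inv * inv,)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims),
                     _parents=(self,))
        denom = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])

        def bk(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape) / denom,)
        out._backward = bk
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bk(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)
        out._backward = bk
        return out

    def slice(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def bk(g):
            full = np.zeros_like(self.data)
            full[key] = g
            return (full,)
        out._backward = bk
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               dilation: int = 1) -> "Tensor":
        """Same-padding (optionally dilated) 1-D convolution, channels-last.

        input (B, L, Cin), weight (K, Cin, Cout) with K odd, bias (Cout,).
        Tap kk sees the input shifted by (kk - K//2) * dilation samples.
        Realized as K shifted batched matmuls, which avoids im2col copies
        and keeps the numpy implementation fast on one core.
        """
        x, w = self.data, weight.data
        B, L, Cin = x.shape
        K, Cin2, Cout = w.shape
        assert Cin == Cin2 and K % 2 == 1 and dilation >= 1
        pad = K // 2
        x2 = np.ascontiguousarray(x).reshape(B * L, Cin)
        out_data = np.zeros((B, L, Cout))
        for kk in range(K):
            yk = (x2 @ w[kk]).reshape(B, L, Cout)
            sh = (kk - pad) * dilation
            if sh >= 0:
                out_data[:, :L - sh, :] += yk[:, sh:, :]
            else:
                out_data[:, -sh:, :] += yk[:, :L + sh, :]
        if bias is not None:
            out_data += bias.data
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(out_data, _parents=parents)

        def bk(g):
            gw = np.empty_like(w)
            gx = np.zeros((B, L, Cin))
            for kk in range(K):
                sh = (kk - pad) * dilation
                if sh >= 0:
                    xv = x[:, sh:, :] if sh else x
                    gv = g[:, :L - sh, :] if sh else g
                else:
                    xv, gv = x[:, :L + sh, :], g[:, -sh:, :]
                nv = xv.shape[1]
                gw[kk] = xv.reshape(B * nv, Cin).T @ gv.reshape(B * nv, Cout)
                gxk = (gv.reshape(B * nv, Cout) @ w[kk].T).reshape(B, nv, Cin)
                if sh >= 0:
                    gx[:, sh:, :] += gxk
                else:
                    gx[:, :L + sh, :] += gxk
            if bias is None:
                return (gx, gw)
            return (gx, gw, g.sum(axis=(0, 1)))
        out._backward = bk
        return out

    # ------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None


class SGD:
    """Plain stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
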