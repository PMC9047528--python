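"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model code builds its forward pass out of the small primitive set defined
here (broadcast arithmetic, batched matmul, softmax, layer normalization,
embedding gather, a fused cross-entropy).  Each primitive records its parents
and a backward closure on a tape; :meth:`Tensor.backward` replays the tape in
reverse topological order.  Every backward rule is gradient-checked against
central finite differences in the test suite.

Only what the encoder-decoder needs is implemented; this is not a general
framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    # -- primitives ----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(
                    _unbroadcast(g @ np.swapaxes(other.value, -1, -2), self.value.shape)
                )
            if other.requires_grad:
                other._accum(
                    _unbroadcast(np.swapaxes(self.value, -1, -2) @ g, other.value.shape)
                )

        out._backward = bwd
        return out

    def reshape(self, *shape):
        src = self.value.shape
        out = Tensor(self.value.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(src))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.value, a, b), parents=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def relu(self):
        keep = self.value > 0
        out = Tensor(self.value * keep, parents=(self,))
        out._backward = lambda g: self._accum(g * keep)
        return out

    def softmax_last(self, additive_mask: np.ndarray | None = None):
        """Softmax over the last axis, with an optional additive mask.

        `additive_mask` is a plain array (0 for allowed, -inf for disallowed)
        added to the logits before normalization; -inf entries yield exactly
        zero weight.  Rows must keep at least one finite entry.
        """
        z = self.value if additive_mask is None else self.value + additive_mask
        zmax = np.max(z, axis=-1, keepdims=True)
        if not np.all(np.isfinite(zmax)):
            raise ValueError("softmax row is fully masked")
        e = np.exp(z - zmax)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bwd(g):
            # d softmax: s * (g - sum(g*s))
            dot = np.sum(g * s, axis=-1, keepdims=True)
            self._accum(s * (g - dot))

        out._backward = bwd
        return out

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-6):
        """Normalize over the last axis, then scale and shift."""
        x = self.value
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gain.value + bias.value, parents=(self, gain, bias))
        n = x.shape[-1]

        def bwd(g):
            if gain.requires_grad:
                gain._accum(_unbroadcast(g * xhat, gain.value.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.value.shape))
            if self.requires_grad:
                gy = g * gain.value
                # standard layer-norm input gradient
                dxhat = gy
                dvar = np.sum(dxhat * xc, axis=-1, keepdims=True) * (-0.5) * inv**3
                dmu = (
                    np.sum(-dxhat * inv, axis=-1, keepdims=True)
                    + dvar * np.mean(-2.0 * xc, axis=-1, keepdims=True)
                )
                self._accum(dxhat * inv + dvar * 2.0 * xc / n + dmu / n)

        out._backward = bwd
        return out

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        keep = (rng.random(self.value.shape) >= rate) / (1.0 - rate)
        out = Tensor(self.value * keep, parents=(self,))
        out._backward = lambda g: self._accum(g * keep)
        return out

    @staticmethod
    def embedding(table: "Tensor", ids: np.ndarray):
        """Row gather `table[ids]` with scatter-add backward."""
        ids = np.asarray(ids)
        out = Tensor(table.value[ids], parents=(table,))

        def bwd(g):
            acc = np.zeros_like(table.value)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, table.value.shape[-1]))
            table._accum(acc)

        out._backward = bwd
        return out

    @staticmethod
    def cross_entropy(logits: "Tensor", targets: np.ndarray, weights: np.ndarray,
                      label_smoothing: float = 0.0):
        """Weighted mean token cross-entropy, fused with log-softmax.

        logits: (..., V); targets: integer array matching logits[...,0] shape;
        weights: same shape as targets (0 for PAD positions).  With label
        smoothing s, the target distribution is (1-s) on the true token and
        s/V uniform.  Returns a scalar Tensor; the weight total must be
        positive.
        """
        z = logits.value
        v = z.shape[-1]
        zmax = z.max(axis=-1, keepdims=True)
        lse = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
        logp = z - lse
        flat_lp = logp.reshape(-1, v)
        flat_t = np.asarray(targets).reshape(-1)
        flat_w = np.asarray(weights, dtype=np.float64).reshape(-1)
        wsum = flat_w.sum()
        if wsum <= 0:
            raise ValueError("cross_entropy needs at least one weighted position")
        s = label_smoothing
        nll_true = -(flat_lp[np.arange(flat_t.size), flat_t] * flat_w).sum() / wsum
        if s > 0:
            nll_unif = -(flat_lp.mean(axis=-1) * flat_w).sum() / wsum
            value = (1 - s) * nll_true + s * nll_unif
        else:
            value = nll_true
        out = Tensor(value, parents=(logits,))

        def bwd(g):
            p = np.exp(flat_lp)
            p[np.arange(flat_t.size), flat_t] -= 1.0 - s
            if s > 0:
                p -= s / v
            p *= (flat_w / wsum)[:, None] * g
            logits._accum(p.reshape(z.shape))

        out._backward = bwd
        return out

    def sum(self):
        out = Tensor(self.value.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.value.shape).copy())
        return out

    # -- backward driver -----------------------------------------------

    def backward(self):
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def constant(x) -> Tensor:
    """A non-trainable graph input."""
    return Tensor(x, requires_grad=False)
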