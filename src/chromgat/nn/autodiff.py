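"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

This is the numerical core under the graph attention network: a small tape of
array operations (matmul, broadcasting arithmetic, gather/scatter by index,
segment max, elementwise nonlinearities, reductions) with exact reverse-mode
gradients.  The op set is deliberately restricted to what message passing on
batched graphs needs; every op's gradient is covered by finite-difference
checks in the test suite.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape (`_unbroadcast`).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], None]] = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Optional[Array] = None) -> None:
        """Reverse-mode sweep from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs (many layers) must not recurse
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
        self._accumulate(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __truediv__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        out._backward = bw
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis: Optional[int] = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = bw
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(self.data > 0, self.data, e), parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, e + alpha))

        out._backward = bw
        return out


def _as_tensor(x: "Tensor | float | Array") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data: Array | float) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data: Array) -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True)


# -- indexed ops over edge/graph structure ---------------------------------


def sparse_matmul(S, St, t: Tensor) -> Tensor:
    """``S @ t`` for a constant sparse matrix ``S`` (with ``St = S.T`` precomputed).

    Covers gather (selection matrix), segment-sum (incidence transpose) and any
    other fixed linear indexing over edge structure; backward is ``St @ grad``.
    """
    out = Tensor(np.asarray(S @ t.data), parents=(t,))

    def bw(g: Array) -> None:
        if t.requires_grad:
            t._accumulate(np.asarray(St @ g))

    out._backward = bw
    return out


def attention_matmul(
    alpha: Tensor,
    z: Tensor,
    src: Array,
    dst: Array,
    n_nodes: int,
) -> Tensor:
    """Attention-weighted neighborhood aggregation as one sparse product.

    Computes ``out[u] = sum_{edges e: dst[e]=u} alpha[e] * z[src[e]]`` by
    assembling the sparse coefficient matrix M with entry alpha_e at
    (dst_e, src_e) — parallel edges sum their coefficients — and returning
    ``M @ z``.  Backward: dz = M.T g; dalpha_e = z[src_e] . g[dst_e].
    """
    import scipy.sparse as sp

    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    M = sp.csr_matrix((alpha.data, (dst, src)), shape=(n_nodes, n_nodes))
    out = Tensor(np.asarray(M @ z.data), parents=(alpha, z))

    def bw(g: Array) -> None:
        if z.requires_grad:
            z._accumulate(np.asarray(M.T @ g))
        if alpha.requires_grad:
            alpha._accumulate((z.data[src] * g[dst]).sum(axis=1))

    out._backward = bw
    return out


def blocked_max(t: Tensor, block: int) -> Tensor:
    """Coordinate-wise max over consecutive row blocks of fixed size.

    Rows are grouped as ``(n_blocks, block, d)``; used for global max pooling
    when every graph contributes exactly ``block`` node rows.  Gradient routes
    to the first argmax row per (block, coordinate).
    """
    n, d = t.data.shape
    if n % block:
        raise ValueError("row count not divisible by block size")
    cube = t.data.reshape(-1, block, d)
    out = Tensor(cube.max(axis=1), parents=(t,))
    arg = cube.argmax(axis=1)  # (n_blocks, d)

    def bw(g: Array) -> None:
        if not t.requires_grad:
            return
        acc = np.zeros_like(cube)
        b_idx = np.arange(cube.shape[0])[:, None]
        c_idx = np.arange(d)[None, :]
        acc[b_idx, arg, c_idx] = g
        t._accumulate(acc.reshape(n, d))

    out._backward = bw
    return out


def gather(t: Tensor, index: Array) -> Tensor:
    """Rows of ``t`` at ``index`` (repetition allowed); grad scatter-adds back."""
    index = np.asarray(index, dtype=int)
    out = Tensor(t.data[index], parents=(t,))

    def bw(g: Array) -> None:
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, index, g)
            t._accumulate(acc)

    out._backward = bw
    return out


def segment_sum(t: Tensor, segment: Array, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given per-row segment ids."""
    segment = np.asarray(segment, dtype=int)
    shape = (n_segments,) + t.data.shape[1:]
    data = np.zeros(shape)
    np.add.at(data, segment, t.data)
    out = Tensor(data, parents=(t,))

    def bw(g: Array) -> None:
        if t.requires_grad:
            t._accumulate(g[segment])

    out._backward = bw
    return out


def segment_max(t: Tensor, segment: Array, n_segments: int) -> Tensor:
    """Per-segment coordinate-wise maximum (global max pooling readout).

    Gradient routes to the (first) argmax row of each segment per coordinate.
    Empty segments yield 0 with no gradient.
    """
    segment = np.asarray(segment, dtype=int)
    d = t.data.shape[1]
    data = np.full((n_segments, d), -np.inf)
    np.maximum.at(data, segment, t.data)
    empty = np.isinf(data)
    data[empty] = 0.0
    # argmax bookkeeping: first row achieving the max per (segment, coord)
    argmax = np.full((n_segments, d), -1, dtype=int)
    for i in range(t.data.shape[0]):  # rows are few (24 per graph); fine
        s = segment[i]
        hit = (t.data[i] >= data[s]) & (argmax[s] == -1) & ~empty[s]
        argmax[s, hit] = i
    out = Tensor(data, parents=(t,))

    def bw(g: Array) -> None:
        if not t.requires_grad:
            return
        acc = np.zeros_like(t.data)
        rows = argmax.ravel()
        cols = np.tile(np.arange(d), n_segments)
        valid = rows >= 0
        np.add.at(acc, (rows[valid], cols[valid]), g.ravel()[valid])
        t._accumulate(acc)

    out._backward = bw
    return out


def segment_softmax(scores: Tensor, segment: Array, n_segments: int) -> Tensor:
    """Softmax of per-edge scores within each destination segment.

    Numerically stabilized by subtracting the (detached) per-segment maximum,
    which leaves both value and gradient unchanged.
    """
    segment = np.asarray(segment, dtype=int)
    m = np.full(n_segments, -np.inf)
    np.maximum.at(m, segment, scores.data)
    m[np.isinf(m)] = 0.0
    shifted = scores - constant(m[segment])
    ex = shifted.exp()
    denom = segment_sum(ex.reshape(-1, 1), segment, n_segments)
    return ex / gather(denom, segment).reshape(-1)


def log_softmax(t: Tensor) -> Tensor:
    """Row-wise log softmax (stabilized with a detached row max)."""
    m = t.data.max(axis=1, keepdims=True)
    shifted = t - constant(m)
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    return shifted - lse


def nll_loss(log_probs: Tensor, labels: Array) -> Tensor:
    """Mean negative log likelihood of the true classes.

    ``log_probs`` holds per-row log-softmax outputs; ``labels`` integer class
    indices in 0..C-1.
    """
    labels = np.asarray(labels, dtype=int)
    n, c = log_probs.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= c:
        raise ValueError("label outside 0..n_classes-1")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    return -(log_probs * constant(onehot)).sum() * (1.0 / n)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
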