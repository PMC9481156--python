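"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the spatiotemporal message-passing
models need: dense affine layers, ReLU, concatenation, row gather/scatter
(segment sums for message aggregation), dropout, fused classification losses,
and an Adam optimizer.  Gradients are available both for parameters (training)
and for leaf inputs (integrated-gradients attribution).

The engine is deliberately small: a :class:`Tensor` records its parents and
one vector-Jacobian product per parent; :func:`backward` runs a topological
sweep.  All correctness-critical pieces are covered by finite-difference
checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "SegmentPlan",
    "backward",
    "linear",
    "relu",
    "concat",
    "gather",
    "segment_sum",
    "mul",
    "add",
    "dropout",
    "softmax",
    "weighted_cross_entropy",
    "mse_to_uniform",
    "softmax_class_sum",
    "MLP",
    "Adam",
]


class Tensor:
    """A numpy array plus autodiff bookkeeping.

    Leaves are created directly; interior nodes are created by the ops below.
    ``grad`` is populated by :func:`backward` for every tensor on a path to a
    leaf with ``requires_grad=True``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        vjps: Sequence[Callable[[np.ndarray], np.ndarray]] = (),
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._vjps = tuple(vjps)
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def backward(loss: Tensor) -> None:
    """Accumulate gradients of a scalar ``loss`` into every reachable tensor."""
    if loss.data.ndim != 0:
        raise ValueError("backward() expects a scalar loss tensor")
    # iterative topological sort (recursion depth is unbounded on deep graphs)
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))
    loss.grad = np.ones((), dtype=loss.data.dtype)
    for node in reversed(topo):
        g = node.grad
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            if parent.grad is None:
                parent.grad = pg
            else:
                parent.grad = parent.grad + pg


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map ``x @ w + b`` with ``b`` broadcast over rows."""
    out = x.data @ w.data + b.data
    return Tensor(
        out,
        parents=(x, w, b),
        vjps=(
            lambda g: g @ w.data.T,
            lambda g: x.data.T @ g,
            lambda g: g.sum(axis=0),
        ),
    )


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    mask = x.data > 0
    return Tensor(out, parents=(x,), vjps=(lambda g: g * mask,))


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two matrices along the feature axis."""
    na = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return Tensor(
        out,
        parents=(a, b),
        vjps=(lambda g: g[:, :na], lambda g: g[:, na:]),
    )


def gather(x: Tensor, idx: np.ndarray, back_plan: "SegmentPlan | None" = None) -> Tensor:
    """Select rows ``x[idx]``; backward scatter-adds into the source rows.

    ``back_plan`` (a SegmentPlan built on ``idx``) makes the backward scatter
    a sorted segment reduction, which is much faster than ``np.add.at``.
    """
    idx = np.asarray(idx)
    n = x.data.shape[0]

    if back_plan is not None:
        vjp = back_plan.apply
    else:

        def vjp(g: np.ndarray) -> np.ndarray:
            out = np.zeros((n,) + g.shape[1:], dtype=g.dtype)
            np.add.at(out, idx, g)
            return out

    return Tensor(x.data[idx], parents=(x,), vjps=(vjp,))


class SegmentPlan:
    """Precomputed scatter plan: sum rows of a source matrix into target rows.

    ``idx[e]`` is the destination row of source row ``e``.  The plan sorts the
    edges once so the forward pass can use ``np.add.reduceat`` (much faster
    than ``np.add.at``); the backward pass is a plain gather.
    """

    __slots__ = ("idx", "n_out", "order", "uniq", "starts", "counts")

    def __init__(self, idx: np.ndarray, n_out: int):
        idx = np.asarray(idx, dtype=np.intp)
        self.idx = idx
        self.n_out = int(n_out)
        self.order = np.argsort(idx, kind="stable")
        sorted_idx = idx[self.order]
        if len(idx):
            self.uniq, self.starts = np.unique(sorted_idx, return_index=True)
        else:
            self.uniq = np.empty(0, dtype=np.intp)
            self.starts = np.empty(0, dtype=np.intp)
        self.counts = np.bincount(idx, minlength=self.n_out).astype(np.intp)

    def apply(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_out, x.shape[1]), dtype=x.dtype)
        if len(self.idx):
            sums = np.add.reduceat(x[self.order], self.starts, axis=0)
            out[self.uniq] = sums
        return out


def segment_sum(x: Tensor, plan: SegmentPlan) -> Tensor:
    """Sum message rows into receiver rows according to ``plan``."""
    return Tensor(plan.apply(x.data), parents=(x,), vjps=(lambda g: g[plan.idx],))


def mul(x: Tensor, c: np.ndarray | float) -> Tensor:
    """Elementwise multiply by a constant (mask, scale); no grad through ``c``."""
    c = np.asarray(c, dtype=x.data.dtype)
    return Tensor(x.data * c, parents=(x,), vjps=(lambda g: g * c,))


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add expects equal shapes")
    return Tensor(a.data + b.data, parents=(a, b), vjps=(lambda g: g, lambda g: g))


def gather2_concat(x: Tensor, idx_a: np.ndarray, idx_b: np.ndarray,
                   plan_a: "SegmentPlan | None" = None, plan_b: "SegmentPlan | None" = None) -> Tensor:
    """``concat([x[idx_a], x[idx_b]], axis=1)`` as a single node.

    The backward pass scatter-adds both halves into the source rows (via the
    segment plans when provided).
    """
    d = x.data.shape[1]
    out = np.empty((len(idx_a), 2 * d), dtype=x.data.dtype)
    out[:, :d] = x.data[idx_a]
    out[:, d:] = x.data[idx_b]

    def vjp(g: np.ndarray) -> np.ndarray:
        ga, gb = g[:, :d], g[:, d:]
        if plan_a is not None:
            acc = plan_a.apply(ga)
        else:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx_a, ga)
        if plan_b is not None:
            acc = acc + plan_b.apply(gb)
        else:
            np.add.at(acc, idx_b, gb)
        return acc

    return Tensor(out, parents=(x,), vjps=(vjp,))


def gathers_concat(a: Tensor, b: Tensor, idx: np.ndarray, plan: "SegmentPlan | None" = None) -> Tensor:
    """``concat([a[idx], b[idx]], axis=1)`` from two sources in one node."""
    da, db = a.data.shape[1], b.data.shape[1]
    out = np.empty((len(idx), da + db), dtype=a.data.dtype)
    out[:, :da] = a.data[idx]
    out[:, da:] = b.data[idx]

    def scatter(g):
        if plan is not None:
            return plan.apply(g)
        acc = np.zeros((a.data.shape[0],) + g.shape[1:], dtype=g.dtype)
        np.add.at(acc, idx, g)
        return acc

    return Tensor(
        out,
        parents=(a, b),
        vjps=(lambda g: scatter(g[:, :da]), lambda g: scatter(g[:, da:])),
    )


def row_update(base: Tensor, idx: np.ndarray, rows: Tensor) -> Tensor:
    """Copy of ``base`` with ``base[idx] = rows`` (idx has unique entries)."""
    idx = np.asarray(idx)
    out = base.data.copy()
    out[idx] = rows.data

    def vjp_base(g: np.ndarray) -> np.ndarray:
        gb = g.copy()
        gb[idx] = 0
        return gb

    return Tensor(out, parents=(base, rows), vjps=(vjp_base, lambda g: g[idx]))


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return x
    dtype = x.data.dtype if x.data.dtype in (np.float32, np.float64) else np.float64
    u = rng.random(x.data.shape, dtype=dtype)
    np.greater_equal(u, p, out=u)  # reuse the buffer as the keep mask
    u /= 1.0 - p
    return mul(x, u)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax(logits: Tensor) -> Tensor:
    p = _softmax(logits.data)

    def vjp(g: np.ndarray) -> np.ndarray:
        dot = (g * p).sum(axis=1, keepdims=True)
        return p * (g - dot)

    return Tensor(p, parents=(logits,), vjps=(vjp,))


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray, weights: np.ndarray) -> Tensor:
    """Mean over targets of ``-w[label] * log softmax(logits)[label]``."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    p = _softmax(logits.data)
    w_row = np.asarray(weights, dtype=logits.data.dtype)[labels]
    eps = np.finfo(p.dtype).tiny
    loss = -(w_row * np.log(np.maximum(p[np.arange(n), labels], eps))).sum() / n

    def vjp(g: np.ndarray) -> np.ndarray:
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels] = 1.0
        return (g * w_row[:, None] * (p - onehot)) / n

    return Tensor(np.asarray(loss, dtype=logits.data.dtype), parents=(logits,), vjps=(vjp,))


def mse_to_uniform(logits: Tensor) -> Tensor:
    """Mean over rows of the squared distance of the softmax scores from 1/3.

    This is the neutral-baseline auxiliary loss: summed over the three fate
    classes, averaged over the null subgraphs in the batch.
    """
    n, k = logits.data.shape
    p = _softmax(logits.data)
    diff = p - 1.0 / k
    loss = (diff**2).sum() / n

    def vjp(g: np.ndarray) -> np.ndarray:
        gp = 2.0 * diff / n  # dL/dp
        dot = (gp * p).sum(axis=1, keepdims=True)
        return g * p * (gp - dot)

    return Tensor(np.asarray(loss, dtype=logits.data.dtype), parents=(logits,), vjps=(vjp,))


def softmax_class_sum(logits: Tensor, cls: int) -> Tensor:
    """Sum over rows of the softmax score of class ``cls``.

    Used by integrated gradients: differentiating this scalar gives each
    target's d(softmax score)/d(input) because distinct targets live in
    disjoint blocks of the batch.
    """
    p = _softmax(logits.data)
    loss = p[:, cls].sum()

    def vjp(g: np.ndarray) -> np.ndarray:
        grad = -p * p[:, cls][:, None]
        grad[:, cls] += p[:, cls]
        return g * grad

    return Tensor(np.asarray(loss, dtype=logits.data.dtype), parents=(logits,), vjps=(vjp,))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class MLP:
    """``n_layer`` hidden blocks (affine + ReLU [+ dropout]) and an affine output.

    Initialization is the standard uniform fan-in scheme,
    U(-1/sqrt(fan_in), 1/sqrt(fan_in)) for both weights and biases.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        hidden: int = 50,
        n_layer: int = 1,
        p_dropout: float = 0.1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if n_layer < 1:
            raise ValueError("n_layer must be >= 1")
        rng = rng or np.random.default_rng()
        self.p_dropout = float(p_dropout)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        dims = [in_dim] + [hidden] * n_layer + [out_dim]
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            w = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(dtype)
            b = rng.uniform(-bound, bound, size=(fan_out,)).astype(dtype)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(b, requires_grad=True))

    def __call__(self, x: Tensor, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Fused forward: the whole MLP is one autodiff node.

        ReLU and (in training) inverted dropout collapse into a single
        elementwise mask per hidden block; the backward pass recomputes all
        parameter and input gradients in one sweep shared by the per-parent
        vector-Jacobian products.
        """
        if train and self.p_dropout > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        ws, bs = self.weights, self.biases
        last = len(ws) - 1
        acts = [x.data]
        masks = []
        h = x.data
        for i, (w, b) in enumerate(zip(ws, bs)):
            z = h @ w.data + b.data
            if i < last:
                m = (z > 0).astype(z.dtype)
                if train and self.p_dropout > 0:
                    u = rng.random(z.shape, dtype=z.dtype if z.dtype in (np.float32, np.float64) else np.float64)
                    np.greater_equal(u, self.p_dropout, out=u)
                    u /= 1.0 - self.p_dropout
                    m *= u
                z = z * m
                masks.append(m)
            h = z
            acts.append(h)

        cache: dict = {}

        def sweep(g: np.ndarray) -> dict:
            if cache.get("seed") is not g:
                gw, gb = [None] * len(ws), [None] * len(ws)
                gz = g
                for i in range(last, -1, -1):
                    gw[i] = acts[i].T @ gz
                    gb[i] = gz.sum(axis=0)
                    ga = gz @ ws[i].data.T
                    gz = ga * masks[i - 1] if i > 0 else ga
                cache.update(seed=g, gw=gw, gb=gb, gx=gz)
            return cache

        parents: list[Tensor] = [x]
        vjps: list[Callable] = [lambda g: sweep(g)["gx"]]
        for i in range(len(ws)):
            parents += [ws[i], bs[i]]
            vjps += [
                (lambda g, i=i: sweep(g)["gw"][i]),
                (lambda g, i=i: sweep(g)["gb"][i]),
            ]
        return Tensor(h, parents=parents, vjps=vjps)

    def parameters(self) -> list[Tensor]:
        return [t for pair in zip(self.weights, self.biases) for t in pair]


class Adam:
    """Adam with conventional defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        scale = self.lr * np.sqrt(b2t) / b1t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= scale * m / (np.sqrt(v) + self.eps * np.sqrt(b2t))
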