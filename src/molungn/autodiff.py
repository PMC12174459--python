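"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps a float64
``ndarray`` together with the closure that propagates an upstream gradient to
its parents.  Only the operations the graph-attention and fusion networks need
are provided, each with an analytically derived backward rule.  All gradients
are checked against central finite differences in the test suite.

The engine is single-threaded and eager; ``backward()`` walks the topologically
sorted tape once and accumulates ``grad`` on every reachable leaf.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "concat",
    "relu",
    "leaky_relu",
    "elu",
    "exp",
    "log",
    "tsum",
    "tmean",
    "masked_softmax",
    "log_softmax",
    "take",
    "gather_rc",
    "gather_axis1",
    "segment_sum_axis1",
    "segment_softmax_axis1",
    "layer_norm",
]


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value : array_like
        Forward value, stored as float64.
    parents : tuple of Tensor
        Direct inputs of the op that produced this node (empty for leaves).
    backward_fn : callable or None
        Receives the upstream gradient (ndarray shaped like ``value``) and
        pushes contributions onto the parents via :func:`_accumulate`.
    """

    __slots__ = ("value", "grad", "_parents", "_backward_fn")

    def __init__(
        self,
        value,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        value = np.asarray(value)
        if value.dtype not in (np.float32, np.float64):
            value = value.astype(np.float64)
        self.value = value
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, leaf={self._backward_fn is None})"

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- autodiff ---------------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, seed: np.ndarray | None = None):
        """Backpropagate from this node.

        ``seed`` defaults to ones (appropriate for scalar losses).
        """
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (epochs of layers)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if seed is None:
            seed = np.ones_like(self.value)
        _accumulate(self, np.asarray(seed, dtype=np.float64))
        for node in reversed(order):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _match_scalar_dtypes(a: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    """Cast a 0-d operand to the other operand's dtype.

    Keeps float32 graphs in float32 when mixed with Python-float constants
    (which otherwise arrive as float64 and upcast everything downstream).
    """
    if a.value.dtype != b.value.dtype:
        if a.value.ndim == 0 and a._backward_fn is None:
            a = Tensor(a.value.astype(b.value.dtype))
        elif b.value.ndim == 0 and b._backward_fn is None:
            b = Tensor(b.value.astype(a.value.dtype))
    return a, b


def _accumulate(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise arithmetic -----------------------------------------------

def add(a, b) -> Tensor:
    a, b = _match_scalar_dtypes(astensor(a), astensor(b))
    out_val = a.value + b.value

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.value.shape))
        _accumulate(b, _unbroadcast(g, b.value.shape))

    return Tensor(out_val, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _match_scalar_dtypes(astensor(a), astensor(b))
    out_val = a.value * b.value

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.value, a.value.shape))
        _accumulate(b, _unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, (a, b), backward)


def matmul(a, b) -> Tensor:
    """``np.matmul`` semantics, including broadcast batch dimensions."""
    a, b = astensor(a), astensor(b)
    out_val = np.matmul(a.value, b.value)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.value, -1, -2))
        gb = np.matmul(np.swapaxes(a.value, -1, -2), g)
        _accumulate(a, _unbroadcast(ga, a.value.shape))
        _accumulate(b, _unbroadcast(gb, b.value.shape))

    return Tensor(out_val, (a, b), backward)


# -- shape manipulation ----------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_val = a.value.reshape(shape)

    def backward(g):
        _accumulate(a, g.reshape(a.value.shape))

    return Tensor(out_val, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_val = a.value.transpose(axes)

    def backward(g):
        _accumulate(a, g.transpose(inv))

    return Tensor(out_val, (a,), backward)


def concat(tensors: Iterable, axis: int = -1) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out_val = np.concatenate([t.value for t in ts], axis=axis)
    sizes = [t.value.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return Tensor(out_val, tuple(ts), backward)


# -- nonlinearities ---------------------------------------------------------

def relu(a) -> Tensor:
    a = astensor(a)
    out_val = np.maximum(a.value, 0.0)

    def backward(g):
        _accumulate(a, g * (a.value > 0.0))

    return Tensor(out_val, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = astensor(a)
    out_val = np.where(a.value > 0.0, a.value, negative_slope * a.value)

    def backward(g):
        _accumulate(a, g * np.where(a.value > 0.0, 1.0, negative_slope))

    return Tensor(out_val, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = astensor(a)
    neg = alpha * np.expm1(np.minimum(a.value, 0.0))
    out_val = np.where(a.value > 0.0, a.value, neg)

    def backward(g):
        _accumulate(a, g * np.where(a.value > 0.0, 1.0, neg + alpha))

    return Tensor(out_val, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    out_val = np.exp(a.value)

    def backward(g):
        _accumulate(a, g * out_val)

    return Tensor(out_val, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out_val = np.log(a.value)

    def backward(g):
        _accumulate(a, g / a.value)

    return Tensor(out_val, (a,), backward)


# -- reductions -------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.value.shape)
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            grad = np.broadcast_to(g, a.value.shape)
        _accumulate(a, np.ascontiguousarray(grad))

    return Tensor(out_val, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        count = a.value.size
    else:
        count = a.value.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


# -- softmax family ----------------------------------------------------------

def masked_softmax(a, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over the entries where ``mask`` is True; zeros elsewhere.

    Rows with no unmasked entry are disallowed (every node keeps a self-loop),
    and the max-subtraction trick guards against overflow.
    """
    a = astensor(a)
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), a.value.shape)
    if not mask.any(axis=axis).all():
        raise ValueError("masked_softmax: a row has an empty neighborhood")
    neg = np.where(mask, a.value, -np.inf)
    m = neg.max(axis=axis, keepdims=True)
    z = np.exp(neg - m)
    denom = z.sum(axis=axis, keepdims=True)
    out_val = z / denom

    def backward(g):
        dot = (g * out_val).sum(axis=axis, keepdims=True)
        _accumulate(a, out_val * (g - dot))

    return Tensor(out_val, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = astensor(a)
    m = a.value.max(axis=axis, keepdims=True)
    shifted = a.value - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_val = shifted - lse
    soft = np.exp(out_val)

    def backward(g):
        _accumulate(a, g - soft * g.sum(axis=axis, keepdims=True))

    return Tensor(out_val, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


# -- indexing ----------------------------------------------------------------

def take(a, indices: np.ndarray, axis: int = 0) -> Tensor:
    a = astensor(a)
    indices = np.asarray(indices)
    out_val = np.take(a.value, indices, axis=axis)

    def backward(g):
        grad = np.zeros_like(a.value)
        if axis == 0:
            np.add.at(grad, indices, g)
        else:  # pragma: no cover - axis 0 is the only use in the package
            sl = [slice(None)] * a.value.ndim
            for k, idx in enumerate(indices):
                sl[axis] = idx
                gsl = [slice(None)] * g.ndim
                gsl[axis] = k
                grad[tuple(sl)] += g[tuple(gsl)]
        _accumulate(a, grad)

    return Tensor(out_val, (a,), backward)


def gather_rc(a, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Pick ``a[rows[i], cols[i]]`` for each i from a 2-D tensor."""
    a = astensor(a)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    out_val = a.value[rows, cols]

    def backward(g):
        grad = np.zeros_like(a.value)
        np.add.at(grad, (rows, cols), g)
        _accumulate(a, grad)

    return Tensor(out_val, (a, ), backward)


def gather_axis1(a, idx: np.ndarray, scatter_perm: np.ndarray,
                 scatter_starts: np.ndarray) -> Tensor:
    """Gather ``a[:, idx]`` with a reduceat-based scatter in the backward.

    ``scatter_perm``/``scatter_starts`` describe how to sum edge gradients
    back per source row: ``perm`` sorts ``idx`` ascending and ``starts``
    marks each row's first position in the sorted order.  Every row of
    ``a``'s axis 1 must appear in ``idx`` at least once (self-loops
    guarantee this for graph use).
    """
    a = astensor(a)
    out_val = a.value[:, idx]

    def backward(g):
        _accumulate(a, np.add.reduceat(g[:, scatter_perm], scatter_starts,
                                       axis=1))

    return Tensor(out_val, (a,), backward)


def segment_sum_axis1(a, starts: np.ndarray, seg_ids: np.ndarray) -> Tensor:
    """Sum contiguous segments along axis 1 (segments must be nonempty)."""
    a = astensor(a)
    out_val = np.add.reduceat(a.value, starts, axis=1)

    def backward(g):
        _accumulate(a, g[:, seg_ids])

    return Tensor(out_val, (a,), backward)


def segment_softmax_axis1(a, starts: np.ndarray,
                          seg_ids: np.ndarray) -> Tensor:
    """Softmax within contiguous segments along axis 1 (max-subtracted)."""
    a = astensor(a)
    m = np.maximum.reduceat(a.value, starts, axis=1)[:, seg_ids]
    z = np.exp(a.value - m)
    denom = np.add.reduceat(z, starts, axis=1)[:, seg_ids]
    out_val = z / denom

    def backward(g):
        t = g * out_val
        s = np.add.reduceat(t, starts, axis=1)[:, seg_ids]
        _accumulate(a, t - out_val * s)

    return Tensor(out_val, (a,), backward)


def layer_norm(a, eps: float = 1e-5) -> Tensor:
    """Per-row feature standardization (no learnable affine)."""
    a = astensor(a)
    mu = a.value.mean(axis=-1, keepdims=True)
    var = a.value.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (a.value - mu) * inv

    def backward(g):
        gm = g.mean(axis=-1, keepdims=True)
        gym = (g * y).mean(axis=-1, keepdims=True)
        _accumulate(a, inv * (g - gm - y * gym))

    return Tensor(y, (a,), backward)
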