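"""Cross-omics label-space fusion (MOVCDN).

For every sample j the m per-view class-probability rows are combined into
the view-correlation discovery tensor

    M_j[a, b, ..., z] = yhat^1_{j,a} * yhat^2_{j,b} * ... * yhat^m_{j,z},

an order-m array of shape C x ... x C whose entries sum to 1 whenever the
inputs are simplex rows.  The tensor is flattened row-major (view 1 is the
slowest-varying axis — fixed so checkpoints are portable), passed through a
two-layer fully connected head (LeakyReLU in between, 128 hidden units by
default) and row-softmaxed into the final class distribution.

m = 2 is supported for dual-omics ablations (tensor C x C, head input C^2);
m = 1 bypasses fusion entirely at the training level.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gat import Linear

__all__ = ["cross_tensor", "cross_tensor_flat", "FusionHead", "fusion_forward"]


def cross_tensor_flat(preds: list) -> Tensor:
    """Batched cross-omics tensors, flattened to (n, C^m) row-major.

    ``preds`` is a list of m (n, C) probability matrices (Tensor or ndarray);
    gradient flows through every input.
    """
    if not 2 <= len(preds) <= 3:
        raise ValueError("fusion needs 2 or 3 views (m=1 bypasses fusion)")
    ts = [ad.astensor(p) for p in preds]
    n, C = ts[0].shape
    for t in ts:
        if t.shape != (n, C):
            raise ValueError(f"prediction shape {t.shape} != ({n}, {C})")
    out = ts[0]
    dim = C
    for t in ts[1:]:
        # (n, dim) x (n, C) -> (n, dim*C) via broadcasted outer product
        out = ad.mul(ad.reshape(out, (n, dim, 1)), ad.reshape(t, (n, 1, C)))
        dim *= C
        out = ad.reshape(out, (n, dim))
    return out


def cross_tensor(rows: list) -> np.ndarray:
    """The discovery tensor for a single sample: outer product of m rows."""
    if not 2 <= len(rows) <= 3:
        raise ValueError("fusion needs 2 or 3 views (m=1 bypasses fusion)")
    C = len(np.asarray(rows[0]).ravel())
    out = np.asarray(rows[0], dtype=float).ravel()
    if out.shape != (C,):
        raise ValueError("rows must be 1-D class distributions")
    for r in rows[1:]:
        r = np.asarray(r, dtype=float).ravel()
        if r.shape != (C,):
            raise ValueError("all rows must have length C")
        out = np.multiply.outer(out, r)
    return out


class FusionHead:
    """Two-layer head mapping the flattened C^m tensor to C class logits."""

    def __init__(self, C: int, m: int, vcdn_features: int,
                 rng: np.random.Generator, slope: float = 0.2,
                 dtype=np.float64):
        if not 2 <= m <= 3:
            raise ValueError("fusion head supports m in {2, 3}")
        self.in_dim = C ** m
        self.C = C
        self.m = m
        self.slope = slope
        self.fc1 = Linear(self.in_dim, vcdn_features, rng, dtype)
        self.fc2 = Linear(vcdn_features, C, rng, dtype)

    def __call__(self, flat) -> Tensor:
        flat = ad.astensor(flat)
        if flat.shape[-1] != self.in_dim:
            raise ValueError(f"fusion input dim {flat.shape[-1]} != C^m = "
                             f"{self.in_dim}")
        return self.fc2(ad.leaky_relu(self.fc1(flat), self.slope))

    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters() + self.fc2.parameters()


def fusion_forward(tensor: np.ndarray, head: FusionHead) -> np.ndarray:
    """Evaluate the head on one discovery tensor -> final class distribution."""
    flat = np.asarray(tensor, dtype=float).reshape(1, -1)
    logits = head(flat)
    return np.exp(ad.log_softmax(logits, axis=-1).value).ravel()
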