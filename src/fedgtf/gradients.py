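"""Fiber-sampled stochastic partial gradients for generalized CP.

The deterministic partial gradient of the generalized CP objective w.r.t.
factor ``A^(d)`` is ``∇_{A^(d)} F = Y_<d> H_d``, where ``Y`` holds the
element-wise loss derivatives ∂f/∂m and ``H_d`` is the mode-d Khatri-Rao
product of the other factors.  The stochastic estimator samples ``|S|``
fibers (columns of ``Y_<d>``) and the matching rows of ``H_d``:

    G^(d) = c · Y_<d>(:, S) H_d(S, :),    c = (I_Π / I_d) / |S|.

The rescaling ``c`` makes the estimator unbiased for the full-entry sum
(disable with ``rescale=False`` to obtain the bare sampled product).  Sampled
fibers include implicit-zero entries — zeros are real data under generalized
CP semantics — yet nothing larger than the ``I_d × |S|`` block is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import ElementLoss, Regularizer, get_loss
from .tensor import FactorSet, SparseTensor, _strides, sampled_khatri_rao_rows

__all__ = [
    "FiberSample",
    "sample_fibers",
    "partial_stochastic_gradient",
    "full_partial_gradient",
]

_ORACLE_MAX_NUMEL = 100_000


@dataclass(frozen=True)
class FiberSample:
    """Distinct 1-based column indices into the mode-``mode`` unfolding."""

    mode: int
    columns: np.ndarray
    ncols_total: int

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=np.int64).ravel()
        if cols.size and (np.unique(cols).size != cols.size):
            raise ValueError("fiber sample contains repeated columns")
        if cols.size and (cols.min() < 1 or cols.max() > self.ncols_total):
            raise IndexError("fiber column index out of range")
        object.__setattr__(self, "columns", cols)

    @property
    def size(self) -> int:
        return self.columns.size


def sample_fibers(
    mode: int, shape: tuple[int, ...], size: int, rng: np.random.Generator
) -> FiberSample:
    """Uniform without-replacement sample of ``size`` mode-``mode`` fibers."""
    _, ncols = _strides(shape, mode)
    if not 1 <= size <= ncols:
        raise ValueError(f"sample size {size} not in 1..{ncols}")
    cols = rng.choice(ncols, size=size, replace=False) + 1
    return FiberSample(mode, cols, ncols)


def partial_stochastic_gradient(
    tensor: SparseTensor,
    factors: FactorSet,
    sample: FiberSample,
    loss: ElementLoss | str,
    reg: Regularizer | None = None,
    *,
    rescale: bool = True,
) -> np.ndarray:
    """Fiber-sampled stochastic gradient ``c · Y_<d>(:,S) H_d(S,:)``.

    Adds the smooth regularizer gradient when ``reg`` is smooth; nonsmooth
    regularizers are handled by the proximal step, not here.
    """
    if isinstance(loss, str):
        loss = get_loss(loss)
    d = sample.mode
    _, ncols = _strides(tensor.shape, d)
    if ncols != sample.ncols_total:
        raise ValueError("fiber sample does not match tensor shape")
    S0 = sample.columns - 1
    H = sampled_khatri_rao_rows(factors, d, sample.columns)      # |S| × R
    M = factors.factors[d - 1] @ H.T                             # I_d × |S|
    X = np.asarray(tensor.unfolding(d)[:, S0].todense())
    Y = loss.derivative(M, X)
    G = Y @ H
    if rescale and sample.size:
        G *= ncols / sample.size
    if reg is not None and reg.smooth:
        G = G + reg.grad(factors.factors[d - 1])
    return G


def full_partial_gradient(
    tensor: SparseTensor,
    factors: FactorSet,
    mode: int,
    loss: ElementLoss | str,
    reg: Regularizer | None = None,
) -> np.ndarray:
    """Exact partial gradient ``Y_<d> H_d`` — a desk-scale test oracle.

    Refuses tensors above ``I_Π = 10^5`` entries: exhaustive fiber evaluation
    is meant for verification, not production updates.
    """
    if tensor.numel > _ORACLE_MAX_NUMEL:
        raise ValueError(
            f"full gradient oracle refuses I_Pi={tensor.numel} > {_ORACLE_MAX_NUMEL}"
        )
    _, ncols = _strides(tensor.shape, mode)
    sample = FiberSample(mode, np.arange(1, ncols + 1), ncols)
    return partial_stochastic_gradient(tensor, factors, sample, loss, reg)
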