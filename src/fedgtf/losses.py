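"""Element-wise generalized losses and factor regularizers.

The generalized CP objective is

    F(A, X) = Σ_{i ∈ I} f(m_i, x_i) + Σ_d r_d(A^(d)),

where ``m_i`` is the CP model value at entry ``i``, ``x_i`` the data value
(zero when the entry is not stored), ``f`` an element-wise loss chosen to
match the data distribution, and ``r_d`` a per-factor regularizer.  Losses
expose the derivative ∂f/∂m, the single quantity the stochastic gradients
need (the entries of the tensor ``Y``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .tensor import FactorSet, SparseTensor, sampled_khatri_rao_rows

__all__ = [
    "ElementLoss",
    "Regularizer",
    "get_loss",
    "get_regularizer",
    "prox",
    "objective",
    "LOSSES",
]


@dataclass(frozen=True)
class ElementLoss:
    """An element-wise loss f(m, x) with its model derivative ∂f/∂m.

    ``value`` and ``derivative`` are vectorized over numpy arrays.
    ``check_data`` validates raw data values (e.g. binary for the logit loss).
    """

    name: str
    value: Callable[[np.ndarray, np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray, np.ndarray], np.ndarray]
    check_data: Callable[[np.ndarray], None]


def _ls_value(m, x):
    return 0.5 * np.square(np.asarray(m) - x)


def _ls_deriv(m, x):
    return np.asarray(m, dtype=float) - x


def _ls_check(values):
    if np.any(np.asarray(values) < 0):
        raise ValueError("least-squares runs expect nonnegative count data")


def _logit_check(values):
    v = np.asarray(values)
    if not np.all((v == 0) | (v == 1)):
        raise ValueError("bernoulli_logit requires binary data in {0, 1}")


def _logit_value(m, x):
    # log(1 + e^m) − x·m, overflow-safe via logaddexp
    return np.logaddexp(0.0, m) - np.asarray(x) * m


def _logit_deriv(m, x):
    # σ(m) − x, saturating without overflow for |m| large
    return expit(m) - x


LOSSES: dict[str, ElementLoss] = {
    "least_squares": ElementLoss("least_squares", _ls_value, _ls_deriv, _ls_check),
    "bernoulli_logit": ElementLoss(
        "bernoulli_logit", _logit_value, _logit_deriv, _logit_check
    ),
}


def get_loss(name: str) -> ElementLoss:
    try:
        return LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(LOSSES)}") from None


@dataclass(frozen=True)
class Regularizer:
    """Factor regularizer r_d with weight λ.

    ``frobenius_sq`` (λ‖A‖_F², smooth, gradient 2λA) and ``l1`` (λ‖A‖₁,
    nonsmooth, soft-threshold prox) are supported; ``none`` is the zero
    regularizer.  A nonsmooth regularizer must admit a closed-form proximal
    operator, which ``l1`` does.
    """

    name: str = "none"
    weight: float = 0.0

    def __post_init__(self):
        if self.name not in ("none", "frobenius_sq", "l1"):
            raise ValueError(f"unknown regularizer {self.name!r}")
        if self.weight < 0:
            raise ValueError("regularizer weight must be nonnegative")

    @property
    def smooth(self) -> bool:
        return self.name != "l1"

    def value(self, A: np.ndarray) -> float:
        if self.name == "none" or self.weight == 0.0:
            return 0.0
        if self.name == "frobenius_sq":
            return float(self.weight * np.sum(np.square(A)))
        return float(self.weight * np.sum(np.abs(A)))

    def grad(self, A: np.ndarray) -> np.ndarray:
        if not self.smooth:
            raise ValueError("nonsmooth regularizer has no gradient; use prox")
        if self.name == "none" or self.weight == 0.0:
            return np.zeros_like(A)
        return 2.0 * self.weight * A


def get_regularizer(name: str, weight: float = 0.0) -> Regularizer:
    return Regularizer(name, weight)


def prox(reg: Regularizer, B: np.ndarray, step: float) -> np.ndarray:
    """Proximal map argmin_A ½‖A−B‖_F² + γ·r(A) with γ = ``step``.

    Soft-thresholding at γλ for ``l1``; identity for ``none``.  Smooth
    regularizers take the gradient path instead, so calling prox on one is a
    contract error.
    """
    if step < 0:
        raise ValueError("prox step must be nonnegative")
    if reg.name == "none":
        return np.asarray(B, dtype=float).copy()
    if reg.smooth:
        raise ValueError(f"prox called with smooth regularizer {reg.name!r}")
    thr = step * reg.weight
    B = np.asarray(B, dtype=float)
    return np.sign(B) * np.maximum(np.abs(B) - thr, 0.0)


def objective(
    tensor: SparseTensor,
    factors: FactorSet,
    loss: ElementLoss | str,
    regs: Sequence[Regularizer] | Regularizer | None = None,
    *,
    sample_columns: int | None = None,
    rng: np.random.Generator | None = None,
    chunk: int = 16384,
) -> float:
    """Full objective Σ_{i∈I} f(m_i, x_i) + Σ_d r_d(A^(d)).

    The sum ranges over **all** ``I_Π`` entries; unstored entries contribute
    with data value zero.  Evaluation streams over mode-1 unfolding columns in
    chunks so no ``I_Π``-sized dense array is held.  With ``sample_columns``
    set, a uniformly-sampled unbiased estimate over that many fibers is
    returned instead of the exact sum (for monitoring large shapes).
    """
    if isinstance(loss, str):
        loss = get_loss(loss)
    if tensor.shape != factors.shape:
        raise ValueError(f"tensor shape {tensor.shape} != factor shape {factors.shape}")
    loss.check_data(tensor.values)

    ncols = tensor.numel // tensor.shape[0]
    unf = tensor.unfolding(1)
    A1 = factors.factors[0]
    if sample_columns is not None:
        if rng is None:
            raise ValueError("sampled objective evaluation needs an rng")
        cols = rng.choice(ncols, size=min(sample_columns, ncols), replace=False)
        scale = ncols / cols.size
    else:
        cols = np.arange(ncols)
        scale = 1.0

    total = 0.0
    for start in range(0, cols.size, chunk):
        sel = np.sort(cols[start : start + chunk])
        H = sampled_khatri_rao_rows(factors, 1, sel + 1)
        M = A1 @ H.T
        X = np.asarray(unf[:, sel].todense())
        total += float(np.sum(loss.value(M, X)))
    total *= scale

    if regs is not None:
        if isinstance(regs, Regularizer):
            regs = [regs] * factors.order
        if len(regs) != factors.order:
            raise ValueError("need one regularizer per mode")
        total += sum(r.value(m) for r, m in zip(regs, factors.factors))
    return total
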