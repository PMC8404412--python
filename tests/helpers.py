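"""Shared test utilities: independent brute-force oracles and data factories."""

from functools import reduce

import numpy as np
from scipy.linalg import khatri_rao

from fedgtf import FactorSet, SparseTensor


def make_sparse(shape, density, rng, binary=False):
    """Random COO tensor with a Bernoulli(density) support mask."""
    mask = rng.random(shape) < density
    coords = np.argwhere(mask) + 1
    if coords.size == 0:
        coords = np.ones((1, len(shape)), dtype=int)
    vals = (np.ones(len(coords)) if binary
            else rng.uniform(0.1, 2.0, size=len(coords)))
    return SparseTensor(shape, coords, vals)


def make_factors(shape, rank, rng, scale=0.5):
    return FactorSet(tuple(rng.normal(size=(I, rank)) * scale for I in shape))


def dense_reconstruction(factors):
    """Explicit sum of R outer products — the CP oracle."""
    out = np.zeros(factors.shape)
    for r in range(factors.rank):
        comp = factors.factors[0][:, r]
        for m in factors.factors[1:]:
            comp = np.multiply.outer(comp, m[:, r])
        out += comp
    return out


def dense_unfolding(dense, mode):
    """Mode-d matricization of a dense array (standard column ordering)."""
    d0 = mode - 1
    return np.reshape(np.moveaxis(dense, d0, 0), (dense.shape[d0], -1), order="F")


def full_khatri_rao(factors, mode):
    """Explicit H_d via scipy's column-wise Kronecker (last operand fastest)."""
    mats = [f for k, f in enumerate(factors.factors) if k != mode - 1]
    return reduce(khatri_rao, mats[::-1])


def brute_objective(tensor, factors, loss_fn):
    """Entry-by-entry objective sum over ALL indices (no regularizer)."""
    dense = tensor.to_dense()
    model = dense_reconstruction(factors)
    total = 0.0
    for idx in np.ndindex(*tensor.shape):
        total += float(loss_fn(model[idx], dense[idx]))
    return total
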