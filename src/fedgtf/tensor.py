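"""Sparse tensors, CP factor sets, and mode-d unfolding index arithmetic.

An order-``D`` tensor ``X`` of shape ``(I_1, ..., I_D)`` is stored in
coordinate (COO) form: a list of 1-based multi-indices and the value at each.
Entries not listed are semantically **zero** — the generalized-CP loss ranges
over all ``I_Π = Π_d I_d`` entries, not only the stored ones.

The mode-``d`` unfolding ``X_<d>`` is the ``I_d × (I_Π/I_d)`` matrix whose
columns are mode-``d`` fibers.  Column indices follow the standard mapping

    j = 1 + Σ_{k≠d} (i_k − 1) J_k,    J_k = Π_{q<k, q≠d} I_q,

i.e. the first non-mode coordinate varies fastest.  All public indices in
this module are 1-based; internal arithmetic is 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "SparseTensor",
    "FactorSet",
    "linear_index",
    "inverse_index",
    "cp_value",
    "sampled_khatri_rao_rows",
    "component_weights",
    "read_coo",
    "write_coo",
    "read_factors",
    "write_factors",
]


def _check_mode(mode: int, order: int) -> None:
    if not 1 <= mode <= order:
        raise IndexError(f"mode {mode} out of range for order-{order} tensor")


def _strides(shape: Sequence[int], mode: int) -> tuple[np.ndarray, int]:
    """Strides J_k for the non-mode dims (ascending k) and the column count."""
    d0 = mode - 1
    J, prod = [], 1
    for k, size in enumerate(shape):
        if k == d0:
            continue
        J.append(prod)
        prod *= size
    return np.asarray(J, dtype=np.int64), prod


def linear_index(multi_index: Sequence[int], mode: int, shape: Sequence[int]) -> int:
    """Map a 1-based multi-index to its 1-based mode-``mode`` unfolding column."""
    _check_mode(mode, len(shape))
    idx = np.asarray(multi_index, dtype=np.int64)
    if idx.shape != (len(shape),):
        raise ValueError("multi_index length does not match tensor order")
    if np.any(idx < 1) or np.any(idx > np.asarray(shape)):
        raise IndexError(f"index {tuple(multi_index)} out of bounds for shape {tuple(shape)}")
    J, _ = _strides(shape, mode)
    non_mode = np.delete(idx, mode - 1)
    return int(1 + np.dot(non_mode - 1, J))


def linear_index_array(coords: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Vectorized :func:`linear_index` over an ``(n, D)`` array of 1-based coords."""
    _check_mode(mode, len(shape))
    J, _ = _strides(shape, mode)
    non_mode = np.delete(coords, mode - 1, axis=1)
    return 1 + (non_mode - 1) @ J


def inverse_index(j: int, mode: int, shape: Sequence[int]) -> tuple[int, ...]:
    """1-based non-mode multi-index ``(i_1,…,i_{d−1},i_{d+1},…,i_D)`` of column ``j``."""
    _check_mode(mode, len(shape))
    J, ncols = _strides(shape, mode)
    if not 1 <= j <= ncols:
        raise IndexError(f"column {j} out of range 1..{ncols}")
    sizes = np.delete(np.asarray(shape, dtype=np.int64), mode - 1)
    return tuple(int(v) for v in ((j - 1) // J) % sizes + 1)


def inverse_index_array(cols: np.ndarray, mode: int, shape: Sequence[int]) -> np.ndarray:
    """Vectorized :func:`inverse_index`: ``(n,)`` 1-based columns -> ``(n, D−1)`` coords."""
    _check_mode(mode, len(shape))
    J, ncols = _strides(shape, mode)
    cols = np.asarray(cols, dtype=np.int64)
    if cols.size and (cols.min() < 1 or cols.max() > ncols):
        raise IndexError("column index out of range")
    sizes = np.delete(np.asarray(shape, dtype=np.int64), mode - 1)
    return ((cols[:, None] - 1) // J[None, :]) % sizes[None, :] + 1


@dataclass(frozen=True)
class SparseTensor:
    """Order-D COO tensor with 1-based coordinates and implicit zeros.

    Parameters
    ----------
    shape
        Positive extents ``(I_1, ..., I_D)``.
    coords
        ``(nnz, D)`` integer array of 1-based multi-indices, duplicate-free.
    values
        ``(nnz,)`` array of entry values.
    """

    shape: tuple[int, ...]
    coords: np.ndarray
    values: np.ndarray
    _unfoldings: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if not shape or any(s < 1 for s in shape):
            raise ValueError(f"invalid shape {shape}")
        coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        values = np.asarray(self.values, dtype=np.float64).ravel()
        if coords.size == 0:
            coords = coords.reshape(0, len(shape))
        if coords.shape != (values.size, len(shape)):
            raise ValueError("coords/values shape mismatch")
        if coords.size:
            if coords.min() < 1 or np.any(coords > np.asarray(shape)):
                raise IndexError("coordinate out of bounds")
            lin = linear_index_array(coords, 1, shape) - 1
            lin = lin * shape[0] + (coords[:, 0] - 1)
            if np.unique(lin).size != lin.size:
                raise ValueError("duplicate coordinates in sparse tensor")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)

    @property
    def order(self) -> int:
        return len(self.shape)

    @property
    def nnz(self) -> int:
        return self.values.size

    @property
    def numel(self) -> int:
        return math.prod(self.shape)

    def unfolding(self, mode: int) -> sparse.csc_matrix:
        """Mode-``mode`` unfolding as a CSC matrix ``I_d × (I_Π/I_d)`` (cached)."""
        _check_mode(mode, self.order)
        if mode not in self._unfoldings:
            _, ncols = _strides(self.shape, mode)
            rows = self.coords[:, mode - 1] - 1
            cols = linear_index_array(self.coords, mode, self.shape) - 1
            mat = sparse.csc_matrix(
                (self.values, (rows, cols)), shape=(self.shape[mode - 1], ncols)
            )
            self._unfoldings[mode] = mat
        return self._unfoldings[mode]

    def to_dense(self, max_numel: int = 10_000_000) -> np.ndarray:
        if self.numel > max_numel:
            raise ValueError(f"refusing to densify {self.numel} entries")
        dense = np.zeros(self.shape)
        dense[tuple(self.coords.T - 1)] = self.values
        return dense


@dataclass(frozen=True)
class FactorSet:
    """A rank-R CP model: one ``I_d × R`` factor matrix per mode.

    The model tensor is ``A = Σ_r A^(1)(:,r) ∘ … ∘ A^(D)(:,r)``.
    """

    factors: tuple[np.ndarray, ...]

    def __post_init__(self):
        mats = tuple(np.asarray(f, dtype=np.float64) for f in self.factors)
        if not mats or any(m.ndim != 2 for m in mats):
            raise ValueError("factors must be a non-empty sequence of matrices")
        ranks = {m.shape[1] for m in mats}
        if len(ranks) != 1:
            raise ValueError(f"factor column counts disagree: {sorted(ranks)}")
        object.__setattr__(self, "factors", mats)

    @property
    def rank(self) -> int:
        return self.factors[0].shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(m.shape[0] for m in self.factors)

    @property
    def order(self) -> int:
        return len(self.factors)

    def copy(self) -> "FactorSet":
        return FactorSet(tuple(m.copy() for m in self.factors))

    def to_dense(self, max_numel: int = 10_000_000) -> np.ndarray:
        """Explicit reconstruction ``Σ_r ∘_d A^(d)(:,r)`` as a dense array."""
        if math.prod(self.shape) > max_numel:
            raise ValueError("reconstruction too large")
        ncols = math.prod(self.shape) // self.shape[0]
        H = sampled_khatri_rao_rows(self, 1, np.arange(1, ncols + 1))
        M = self.factors[0] @ H.T
        return np.reshape(M, self.shape, order="F")


def cp_value(factors: FactorSet, multi_index: Sequence[int]) -> float:
    """Model value ``Σ_r Π_d A^(d)(i_d, r)`` at a 1-based multi-index."""
    idx = tuple(int(i) for i in multi_index)
    if len(idx) != factors.order:
        raise ValueError("multi_index length does not match factor order")
    shape = factors.shape
    if any(not 1 <= i <= s for i, s in zip(idx, shape)):
        raise IndexError(f"index {idx} out of bounds for shape {shape}")
    row = np.ones(factors.rank)
    for d, i in enumerate(idx):
        row = row * factors.factors[d][i - 1]
    return float(row.sum())


def sampled_khatri_rao_rows(
    factors: FactorSet, mode: int, sample: Iterable[int]
) -> np.ndarray:
    """Rows of the mode-``mode`` Khatri-Rao product selected by 1-based columns.

    Row ``s`` is the Hadamard product of the non-mode factor rows addressed by
    ``inverse_index(sample[s])``; equal to the corresponding rows of the full
    product ``H_d = A^(D) ⊙ … ⊙ A^(d+1) ⊙ A^(d−1) ⊙ … ⊙ A^(1)`` without ever
    materializing it.
    """
    cols = np.asarray(list(sample) if not isinstance(sample, np.ndarray) else sample,
                      dtype=np.int64).ravel()
    if cols.size == 0:
        return np.empty((0, factors.rank))
    idx = inverse_index_array(cols, mode, factors.shape)
    non_mode = [f for k, f in enumerate(factors.factors) if k != mode - 1]
    H = non_mode[0][idx[:, 0] - 1].copy()
    for k in range(1, len(non_mode)):
        H *= non_mode[k][idx[:, k] - 1]
    return H


def component_weights(factors: FactorSet) -> np.ndarray:
    """Component weights λ_r = Π_d ‖A^(d)(:,r)‖₂ (phenotype importance)."""
    norms = np.stack([np.linalg.norm(m, axis=0) for m in factors.factors])
    return norms.prod(axis=0)


# ---------------------------------------------------------------------------
# Text I/O: COO tensor files and delimited factor matrices
# ---------------------------------------------------------------------------

def write_coo(tensor: SparseTensor, path_or_file) -> None:
    """Write ``shape I1 … ID`` header then ``i1 … iD value`` lines (1-based)."""
    close, fh = _open(path_or_file, "w")
    try:
        fh.write("shape " + " ".join(str(s) for s in tensor.shape) + "\n")
        for row, val in zip(tensor.coords, tensor.values):
            fh.write(" ".join(str(int(i)) for i in row) + f" {float(val)!r}\n")
    finally:
        if close:
            fh.close()


def read_coo(path_or_file) -> SparseTensor:
    """Parse the COO text format produced by :func:`write_coo`."""
    close, fh = _open(path_or_file, "r")
    try:
        header = fh.readline().split()
        if not header or header[0] != "shape":
            raise ValueError("COO file must start with a 'shape I1 ... ID' line")
        shape = tuple(int(s) for s in header[1:])
        coords, values = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(shape) + 1:
                raise ValueError(f"line {lineno}: expected {len(shape)} indices + value")
            coords.append([int(p) for p in parts[:-1]])
            values.append(float(parts[-1]))
        coords_arr = np.asarray(coords, dtype=np.int64).reshape(len(values), len(shape))
        return SparseTensor(shape, coords_arr, np.asarray(values))
    finally:
        if close:
            fh.close()


def write_factors(factors: FactorSet, prefix: str) -> list[str]:
    """One whitespace-delimited text file per mode: ``<prefix>_mode<d>.txt``."""
    paths = []
    for d, mat in enumerate(factors.factors, start=1):
        path = f"{prefix}_mode{d}.txt"
        np.savetxt(path, mat)
        paths.append(path)
    return paths


def read_factors(prefix: str, order: int) -> FactorSet:
    mats = [np.loadtxt(f"{prefix}_mode{d}.txt", ndmin=2) for d in range(1, order + 1)]
    return FactorSet(tuple(mats))


def _open(path_or_file, flags: str) -> tuple[bool, IO]:
    if hasattr(path_or_file, "read") or hasattr(path_or_file, "write"):
        return False, path_or_file
    return True, open(path_or_file, flags)
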