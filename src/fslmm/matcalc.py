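"""Vectorization operators and structural matrices for matrix calculus.

Everything here follows the column-major ("stack the columns") convention:
``vec`` stacks columns, ``vech`` stacks the on-and-below-diagonal elements
column by column.  The structural matrices are the classical duplication
(:math:`\\mathcal{D}_k`), elimination (:math:`\\mathcal{L}_k`), commutation
(:math:`K_{m,n}`) and symmetrizer (:math:`N_k`) matrices of Magnus-Neudecker
matrix calculus, satisfying

.. math::

    \\mathcal{D}_k \\operatorname{vech}(A) = \\operatorname{vec}(A)
    \\quad (A = A'), \\qquad
    \\mathcal{L}_k \\operatorname{vec}(L) = \\operatorname{vech}(L)
    \\quad (L \\text{ lower triangular}), \\qquad
    K_{m,n} \\operatorname{vec}(A') = \\operatorname{vec}(A),

with :math:`N_k = (I_{k^2} + K_{k,k})/2` implementing symmetrization in
vectorized form.  Dimensions stay small (the number of random effects per
factor), so the matrices are built as dense 0/1 arrays and cached per
dimension.  Permutations that act on large vectors are stored as index
vectors and applied by gather, never as dense matrices.

The module also provides the two fast summation primitives used throughout
the estimation code: a reshape-based generalized vectorization (``vec_m``)
that turns sums of block cross-products into a single matrix product, and a
permuted-reshape evaluation of Kronecker-product sums
:math:`\\sum_{i,j} G_{i,j} \\otimes H_{i,j}` that avoids any per-block loop.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "vec",
    "unvec",
    "vech",
    "unvech",
    "vech_indices",
    "duplication_matrix",
    "elimination_matrix",
    "commutation_matrix",
    "symmetrizer_matrix",
    "kron_perm_vector",
    "vec_m",
    "block_vec_tilde",
    "kron_sum_vectorized",
]


def vec(a: np.ndarray) -> np.ndarray:
    """Stack the columns of ``a`` into a 1-d array (column-major)."""
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError("vec expects a matrix")
    return a.reshape(-1, order="F")


def unvec(v: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Inverse of :func:`vec` for a ``rows x cols`` matrix."""
    return np.asarray(v).reshape(rows, cols, order="F")


def vech_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) indices of the lower triangle in column-major order."""
    cols, rows = np.triu_indices(k)  # upper triangle row-major == lower col-major
    return rows, cols


def vech(a: np.ndarray) -> np.ndarray:
    """Stack the on-and-below-diagonal elements of square ``a`` column-major."""
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("vech expects a square matrix")
    r, c = vech_indices(a.shape[0])
    return a[r, c]


def unvech(v: np.ndarray, k: int, symmetric: bool = True) -> np.ndarray:
    """Rebuild a ``k x k`` matrix from its half-vectorization.

    With ``symmetric=True`` (default) the strict lower triangle is mirrored
    above the diagonal; otherwise a lower-triangular matrix is returned.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (k * (k + 1) // 2,):
        raise ValueError(f"vech vector has wrong length for dimension {k}")
    out = np.zeros((k, k))
    r, c = vech_indices(k)
    out[r, c] = v
    if symmetric:
        strict = r != c
        out[c[strict], r[strict]] = v[strict]
    return out


def _check_dim(k: int) -> None:
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"dimension must be a positive integer, got {k!r}")


@lru_cache(maxsize=None)
def duplication_matrix(k: int) -> np.ndarray:
    """Duplication matrix D_k with D_k vech(A) = vec(A) for symmetric A."""
    _check_dim(k)
    m = k * (k + 1) // 2
    out = np.zeros((k * k, m))
    r, c = vech_indices(k)
    for idx, (i, j) in enumerate(zip(r, c)):
        out[j * k + i, idx] = 1.0
        out[i * k + j, idx] = 1.0
    return out


@lru_cache(maxsize=None)
def elimination_matrix(k: int) -> np.ndarray:
    """Elimination matrix L_k with L_k vec(A) = vech(A)."""
    _check_dim(k)
    m = k * (k + 1) // 2
    out = np.zeros((m, k * k))
    r, c = vech_indices(k)
    out[np.arange(m), c * k + r] = 1.0
    return out


@lru_cache(maxsize=None)
def commutation_matrix(m: int, n: int) -> np.ndarray:
    """Commutation matrix K_{m,n} with K_{m,n} vec(A') = vec(A), A (m x n)."""
    _check_dim(m)
    _check_dim(n)
    out = np.zeros((m * n, m * n))
    r = np.repeat(np.arange(m), n)
    c = np.tile(np.arange(n), m)
    out[c * m + r, r * n + c] = 1.0
    return out


@lru_cache(maxsize=None)
def symmetrizer_matrix(k: int) -> np.ndarray:
    """N_k = (I + K_{k,k})/2, so N_k vec(A) = vec(A + A')/2."""
    _check_dim(k)
    return 0.5 * (np.eye(k * k) + commutation_matrix(k, k))


@lru_cache(maxsize=None)
def kron_perm_vector(n1: int, n2: int) -> np.ndarray:
    """Gather indices implementing vec(G (x) H) = [vec(G) (x) vec(H)][perm].

    For ``G``, ``H`` both ``n1 x n2``, the permutation matrix
    :math:`(I_{n2} \\otimes K_{n1,n2} \\otimes I_{n1})` relating
    ``vec(G) (x) vec(H)`` to ``vec(G (x) H)`` is stored as the index vector
    ``perm`` such that ``vec(G (x) H) = (vec(G) (x) vec(H))[perm]``.
    """
    _check_dim(n1)
    _check_dim(n2)
    rg, cg, rh, ch = np.meshgrid(
        np.arange(n1), np.arange(n2), np.arange(n1), np.arange(n2), indexing="ij"
    )
    dest = (cg * n2 + ch) * n1 * n1 + rg * n1 + rh
    src = (cg * n1 + rg) * (n1 * n2) + ch * n1 + rh
    perm = np.empty(n1 * n1 * n2 * n2, dtype=np.intp)
    perm[dest.ravel()] = src.ravel()
    return perm


def vec_m(mat: np.ndarray, m: int) -> np.ndarray:
    """Generalized vectorization: stack the m-column partitions vertically.

    ``[M_1, M_2, ..., M_c] -> [M_1', M_2', ..., M_c']'`` (the transpose of
    the row of transposed partitions, i.e. the partitions stacked on top of
    each other).  ``vec_1`` coincides with the ordinary column-stacking
    ``vec``; a single partition returns ``M`` unchanged.  Implemented
    purely by reshape.  The identity

        sum_i A_i B_i' = vec_{m1}(A')' vec_{m1}(B')

    (``A``, ``B`` vertical stacks of ``(m1 x m2)`` blocks) turns per-level
    cross-product sums into one matrix product.
    """
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError("vec_m expects a matrix")
    a, b = mat.shape
    if m < 1 or b % m:
        raise ValueError(f"column count {b} not divisible by partition width {m}")
    c = b // m
    return np.transpose(mat.reshape(a, c, m), (1, 0, 2)).reshape(c * a, m)


def block_vec_tilde(mat: np.ndarray, block_rows: int, block_cols: int) -> np.ndarray:
    """Row-major block scan of ``mat``; each output row is vec(block)'.

    ``mat`` is partitioned into a grid of ``block_rows x block_cols`` blocks;
    block (i, j) contributes row ``i * c2 + j`` equal to the transposed
    column-major vectorization of the block.
    """
    mat = np.asarray(mat)
    rows, cols = mat.shape
    if block_rows < 1 or block_cols < 1 or rows % block_rows or cols % block_cols:
        raise ValueError("matrix does not partition evenly into the given blocks")
    c1, c2 = rows // block_rows, cols // block_cols
    r = mat.reshape(c1, block_rows, c2, block_cols)
    return np.transpose(r, (0, 2, 3, 1)).reshape(c1 * c2, block_rows * block_cols)


def kron_sum_vectorized(
    g: np.ndarray, h: np.ndarray, block_rows: int, block_cols: int
) -> np.ndarray:
    """Evaluate sum_{i,j} G_{i,j} (x) H_{i,j} without looping over blocks.

    ``g`` and ``h`` are identically partitioned into blocks of shape
    ``(block_rows, block_cols)``.  The sum is computed as the permuted
    ``vec(H~' G~)`` where ``~`` is :func:`block_vec_tilde`, the permutation
    being the cached index vector of :func:`kron_perm_vector`.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ValueError("G and H must have identical shapes")
    n1, n2 = block_rows, block_cols
    gt = block_vec_tilde(g, n1, n2)
    ht = block_vec_tilde(h, n1, n2)
    v = vec(ht.T @ gt)[kron_perm_vector(n1, n2)]
    return unvec(v, n1 * n1, n2 * n2)
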