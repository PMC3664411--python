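"""Small linear-algebra utilities: vec, vec-permutation, block diagonals.

These are the notation primitives of the age-by-stage construction
(unit vectors, single-entry matrices, the vec operator and its
permutation matrix). They are internal plumbing, not domain objects.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["vec", "unvec", "vec_permutation_matrix", "repeat_block_diag"]


def vec(X: np.ndarray) -> np.ndarray:
    """Stack the columns of a matrix into a single vector."""
    return np.asarray(X).reshape(-1, order="F")


def unvec(x: np.ndarray, m: int, n: int) -> np.ndarray:
    """Inverse of :func:`vec`: reshape a length-``m*n`` vector to ``m x n``."""
    return np.asarray(x).reshape((m, n), order="F")


def vec_permutation_matrix(m: int, n: int) -> sp.csr_matrix:
    """Vec-permutation (commutation) matrix ``K_{m,n}``.

    For any ``m x n`` matrix ``N``, ``K_{m,n} @ vec(N) == vec(N.T)``.
    Equivalently ``K = sum_{ij} E_ij (x) E_ij^T`` over the single-entry
    matrices ``E_ij`` of shape ``m x n``; the explicit index form used
    here is the standard sparse construction of that sum.

    Parameters
    ----------
    m, n : int
        Row and column dimension of the matrices being vectorized.
    """
    if m < 1 or n < 1:
        raise ValueError(f"dimensions must be positive, got ({m}, {n})")
    i, j = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    rows = (j + i * n).ravel()  # position of (i, j) in vec(N^T)
    cols = (i + j * m).ravel()  # position of (i, j) in vec(N)
    data = np.ones(m * n)
    return sp.csr_matrix((data, (rows, cols)), shape=(m * n, m * n))


def repeat_block_diag(B, copies: int) -> sp.csr_matrix:
    """Block diagonal matrix with ``copies`` repetitions of ``B``."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return sp.kron(sp.identity(copies, format="csr"), sp.csr_matrix(B), format="csr")
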