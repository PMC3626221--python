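"""Row-action (Kaczmarz/ART) and simultaneous (SART) algebraic solvers.

Both solve ``y = A mu`` iteratively.  ART sweeps the rows of ``A`` in order,
projecting the iterate onto each ray's hyperplane; SART applies all rays at
once with row-sum scaling of the residual and column-sum scaling after the
adjoint.  Rows with zero norm (rays missing the image) are skipped.

``kaczmarz_sweeps`` and ``sirt_iterations`` are the computational cores and
accept any scipy sparse (or dense) matrix; ``art_reconstruct`` and
``sart_reconstruct`` wrap them for the CT types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ImageGrid, Sinogram, SystemMatrix
from .results import ReconResult

__all__ = [
    "AlgebraicConfig",
    "kaczmarz_sweeps",
    "sirt_iterations",
    "art_reconstruct",
    "sart_reconstruct",
]


@dataclass
class AlgebraicConfig:
    relaxation: float = 1.0
    n_iterations: int = 30
    initial: np.ndarray | None = None
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.relaxation < 2:
            raise ValueError(f"relaxation must be in (0, 2), got {self.relaxation}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")


def kaczmarz_sweeps(
    matrix,
    b: np.ndarray,
    n_sweeps: int,
    relaxation: float = 1.0,
    x0: np.ndarray | None = None,
    nonnegative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Kaczmarz iteration: for each row i in order 0..m-1,
    ``x <- x + lam * (b_i - <a_i, x>) / ||a_i||^2 * a_i``.

    One sweep passes through all rows; rows with zero norm are skipped.
    Returns the final iterate and the residual norm after each sweep.
    """
    mat = sp.csr_matrix(matrix, dtype=float)
    if mat.nnz == 0:
        raise ValueError("matrix is all zeros")
    b = np.asarray(b, dtype=float).ravel()
    if b.size != mat.shape[0]:
        raise ValueError(f"rhs has {b.size} entries, expected {mat.shape[0]}")
    x = np.zeros(mat.shape[1]) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    if x.size != mat.shape[1]:
        raise ValueError("initial iterate has wrong size")

    indptr, indices, data = mat.indptr, mat.indices, mat.data
    sq_norms = np.asarray(mat.multiply(mat).sum(axis=1)).ravel()
    active = np.flatnonzero(sq_norms > 0)

    residuals = np.empty(n_sweeps)
    for sweep in range(n_sweeps):
        for i in active:
            lo, hi = indptr[i], indptr[i + 1]
            cols = indices[lo:hi]
            a = data[lo:hi]
            r = b[i] - a.dot(x[cols])
            x[cols] += relaxation * r / sq_norms[i] * a
        if nonnegative:
            np.maximum(x, 0.0, out=x)
        residuals[sweep] = np.linalg.norm(mat.dot(x) - b)
    return x, residuals


def sirt_iterations(
    matrix,
    b: np.ndarray,
    n_iterations: int,
    relaxation: float = 1.0,
    x0: np.ndarray | None = None,
    nonnegative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """SART iteration
    ``x <- x + lam * V^{-1} A^T W^{-1} (b - A x)`` with
    ``W = diag(row sums)`` scaling the residual and ``V = diag(column sums)``
    scaling the backprojected correction; zero sums are excluded.

    Returns the final iterate and the residual norm after each iteration.
    """
    mat = sp.csr_matrix(matrix, dtype=float)
    if mat.nnz == 0:
        raise ValueError("matrix is all zeros")
    b = np.asarray(b, dtype=float).ravel()
    if b.size != mat.shape[0]:
        raise ValueError(f"rhs has {b.size} entries, expected {mat.shape[0]}")
    x = np.zeros(mat.shape[1]) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()

    # Row/column sums of |A|; for CT matrices entries are nonnegative already.
    abs_mat = abs(mat)
    row_sums = np.asarray(abs_mat.sum(axis=1)).ravel()
    col_sums = np.asarray(abs_mat.sum(axis=0)).ravel()
    inv_row = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    inv_col = np.divide(1.0, col_sums, out=np.zeros_like(col_sums), where=col_sums > 0)

    residuals = np.empty(n_iterations)
    for it in range(n_iterations):
        r = b - mat.dot(x)
        x += relaxation * inv_col * mat.T.dot(inv_row * r)
        if nonnegative:
            np.maximum(x, 0.0, out=x)
        residuals[it] = np.linalg.norm(mat.dot(x) - b)
    return x, residuals


def _wrap(A: SystemMatrix, x: np.ndarray, residuals: np.ndarray, n_iter: int) -> ReconResult:
    side = A.grid_side
    return ReconResult(
        ImageGrid(x.reshape(side, side), A.pixel_size),
        cost_trace=residuals,
        iterations_run=n_iter,
        converged=bool(residuals[-1] < 1e-10),
    )


def art_reconstruct(A: SystemMatrix, y: Sinogram, cfg: AlgebraicConfig | None = None) -> ReconResult:
    """ART reconstruction: ``cfg.n_iterations`` Kaczmarz sweeps (default 30)."""
    cfg = cfg or AlgebraicConfig()
    x, residuals = kaczmarz_sweeps(
        A.matrix, y.ravel(), cfg.n_iterations, cfg.relaxation, cfg.initial, cfg.nonnegative
    )
    return _wrap(A, x, residuals, cfg.n_iterations)


def sart_reconstruct(A: SystemMatrix, y: Sinogram, cfg: AlgebraicConfig | None = None) -> ReconResult:
    """SART reconstruction (default 150 simultaneous iterations)."""
    cfg = cfg or AlgebraicConfig(n_iterations=150)
    x, residuals = sirt_iterations(
        A.matrix, y.ravel(), cfg.n_iterations, cfg.relaxation, cfg.initial, cfg.nonnegative
    )
    return _wrap(A, x, residuals, cfg.n_iterations)
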