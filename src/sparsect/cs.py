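"""Compressed-sensing reconstruction by smoothed nonlinear conjugate gradient.

Minimizes

    J(mu) = lambda1 * ||mu||_TV + lambda2 * ||W mu||_1 + ||A mu - y||_2^2

where ``W`` is an orthonormal 2D wavelet transform and the TV term is the
isotropic sum of gradient magnitudes.  Absolute values are smoothed as
``|x| ~ sqrt(x^2 + xi)`` so the objective is differentiable; the same
smoothing is used in the objective and its gradient, which makes the
Armijo backtracking descent guarantee exact.  The TV-only method is the
``lambda2 = 0`` special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import ImageGrid, Sinogram, SystemMatrix
from .results import ReconResult
from .wavelets import WaveletOperator

__all__ = [
    "CsConfig",
    "smoothed_abs",
    "smoothed_abs_grad",
    "tv_norm",
    "tv_gradient",
    "cost",
    "cost_gradient",
    "nlcg_reconstruct",
    "param_search",
    "alternating_param_search",
]


@dataclass
class CsConfig:
    """Solver configuration; defaults follow common practice where the
    method itself leaves them open."""

    lambda1: float = 0.001
    lambda2: float = 0.0005
    xi: float = 1e-15
    max_iterations: int = 150
    wavelet_family: str = "db4"
    wavelet_levels: int = 4
    initial_step: float = 1.0
    step_shrink: float = 0.5
    sufficient_decrease: float = 1e-4
    max_backtracks: int = 20
    grad_tolerance: float = 1e-6
    trial_step: str = "fixed"
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be nonnegative")
        if not 0 < self.step_shrink < 1:
            raise ValueError("step_shrink must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.trial_step not in ("fixed", "quadratic"):
            raise ValueError("trial_step must be 'fixed' or 'quadratic'")


def smoothed_abs(x: np.ndarray | float, xi: float) -> np.ndarray | float:
    """Smooth surrogate ``sqrt(x^2 + xi)`` for ``|x|``."""
    return np.sqrt(np.square(x) + xi)


def smoothed_abs_grad(x: np.ndarray | float, xi: float) -> np.ndarray | float:
    """Derivative ``x / sqrt(x^2 + xi)`` of the smoothed absolute value."""
    return x / np.sqrt(np.square(x) + xi)


def _forward_diffs(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with replicate (Neumann) boundary: the last
    column (resp. row) of the x (resp. y) difference is zero."""
    dx = np.zeros_like(img)
    dy = np.zeros_like(img)
    dx[:, :-1] = img[:, 1:] - img[:, :-1]
    dy[:-1, :] = img[1:, :] - img[:-1, :]
    return dx, dy


def tv_norm(img: np.ndarray, xi: float = 0.0) -> float:
    """Isotropic total variation ``sum sqrt(dx^2 + dy^2 + xi)``.

    ``xi = 0`` gives the exact TV used for reporting; a positive ``xi``
    gives the smoothed TV used inside the objective.
    """
    img = np.asarray(img, dtype=float)
    dx, dy = _forward_diffs(img)
    return float(np.sum(np.sqrt(dx * dx + dy * dy + xi)))


def tv_gradient(img: np.ndarray, xi: float) -> np.ndarray:
    """Gradient of the smoothed TV: negative discrete divergence of the
    normalized gradient field, adjoint-consistent with ``tv_norm``."""
    if xi <= 0:
        raise ValueError("xi must be positive for the TV gradient")
    img = np.asarray(img, dtype=float)
    dx, dy = _forward_diffs(img)
    w = 1.0 / np.sqrt(dx * dx + dy * dy + xi)
    px = dx * w
    py = dy * w
    grad = -(px + py)
    grad[:, 1:] += px[:, :-1]
    grad[1:, :] += py[:-1, :]
    return grad


def _wavelet_for(cfg: CsConfig, side: int) -> WaveletOperator | None:
    if cfg.lambda2 == 0:
        return None
    levels = cfg.wavelet_levels
    padded = 1 << max(int(np.ceil(np.log2(side))), 0)
    # Cap the depth on tiny images rather than erroring out.
    while levels > 1 and padded % (1 << levels) != 0:
        levels -= 1
    return WaveletOperator(side, cfg.wavelet_family, levels)


def cost(
    mu: np.ndarray,
    A: SystemMatrix,
    y: Sinogram,
    cfg: CsConfig,
    wavelet: WaveletOperator | None = None,
) -> float:
    """Objective ``lambda1*TV_xi(mu) + lambda2*sum(sabs(W mu)) + ||A mu - y||^2``."""
    mu = np.asarray(mu, dtype=float)
    r = A.dot(mu.ravel()) - y.ravel()
    val = float(r.dot(r))
    if cfg.lambda1 > 0:
        val += cfg.lambda1 * tv_norm(mu, cfg.xi)
    if cfg.lambda2 > 0:
        w = wavelet if wavelet is not None else _wavelet_for(cfg, mu.shape[0])
        val += cfg.lambda2 * float(np.sum(smoothed_abs(w.forward(mu), cfg.xi)))
    return val


def cost_gradient(
    mu: np.ndarray,
    A: SystemMatrix,
    y: Sinogram,
    cfg: CsConfig,
    wavelet: WaveletOperator | None = None,
) -> np.ndarray:
    """Gradient ``lambda1*grad TV + lambda2*W^T sabs'(W mu) + 2 A^T(A mu - y)``."""
    mu = np.asarray(mu, dtype=float)
    r = A.dot(mu.ravel()) - y.ravel()
    grad = 2.0 * A.rmatvec(r).reshape(mu.shape)
    if cfg.lambda1 > 0:
        grad += cfg.lambda1 * tv_gradient(mu, cfg.xi)
    if cfg.lambda2 > 0:
        w = wavelet if wavelet is not None else _wavelet_for(cfg, mu.shape[0])
        coeffs = w.forward(mu)
        grad += cfg.lambda2 * w.inverse(smoothed_abs_grad(coeffs, cfg.xi))
    return grad


def nlcg_reconstruct(A: SystemMatrix, y: Sinogram, cfg: CsConfig | None = None) -> ReconResult:
    """Polak-Ribiere+ nonlinear conjugate gradient with Armijo backtracking.

    The cost trace (including the initial point) is nonincreasing by
    construction; iteration stops at ``max_iterations``, when the gradient
    norm falls below ``grad_tolerance * (1 + |J|)``, or when the line
    search can find no decreasing step.
    """
    cfg = cfg or CsConfig()
    side = A.grid_side
    if cfg.initial is None:
        x = np.zeros((side, side))
    else:
        x = np.asarray(cfg.initial, dtype=float).reshape(side, side).copy()

    wavelet = _wavelet_for(cfg, side)
    b = y.ravel()

    def reg_terms(im: np.ndarray) -> float:
        val = 0.0
        if cfg.lambda1 > 0:
            val += cfg.lambda1 * tv_norm(im, cfg.xi)
        if cfg.lambda2 > 0:
            val += cfg.lambda2 * float(np.sum(smoothed_abs(wavelet.forward(im), cfg.xi)))
        return val

    def reg_grad(im: np.ndarray) -> np.ndarray:
        g = np.zeros_like(im)
        if cfg.lambda1 > 0:
            g += cfg.lambda1 * tv_gradient(im, cfg.xi)
        if cfg.lambda2 > 0:
            g += cfg.lambda2 * wavelet.inverse(smoothed_abs_grad(wavelet.forward(im), cfg.xi))
        return g

    # Cache A x so line-search trials cost no extra projections:
    # ||A(x + a d) - y||^2 = ||r + a (A d)||^2 with r = A x - y.
    r = A.dot(x.ravel()) - b
    J = float(r.dot(r)) + reg_terms(x)
    if not np.isfinite(J):
        raise FloatingPointError("non-finite initial cost")
    g = 2.0 * A.rmatvec(r).reshape(x.shape) + reg_grad(x)
    d = -g
    trace = [J]
    alpha_prev = cfg.initial_step
    converged = False
    iters = 0

    for iters in range(1, cfg.max_iterations + 1):
        gnorm = np.linalg.norm(g)
        if gnorm <= cfg.grad_tolerance * (1.0 + abs(J)):
            converged = True
            iters -= 1
            break

        slope = float(np.sum(g * d))
        if slope >= 0:  # not a descent direction: restart on steepest descent
            d = -g
            slope = -float(gnorm**2)

        Ad = A.dot(d.ravel())
        Ad_sq = float(Ad.dot(Ad))
        # Trial step, safeguarded by Armijo backtracking below.  "fixed":
        # restart from the configured initial step, warm-started by one
        # growth factor from the previously accepted step (plain
        # backtracking).  "quadratic": exact minimizer of the quadratic
        # data term along d (exact line search when the regularizers are
        # off), for high-accuracy solves.
        if cfg.trial_step == "quadratic" and Ad_sq > 0:
            alpha = -slope / (2.0 * Ad_sq)
        else:
            alpha = min(cfg.initial_step, alpha_prev / cfg.step_shrink)
        accepted = False
        for _ in range(cfg.max_backtracks + 1):
            x_new = x + alpha * d
            r_new = r + alpha * Ad
            J_new = float(r_new.dot(r_new)) + reg_terms(x_new)
            if np.isfinite(J_new) and J_new <= J + cfg.sufficient_decrease * alpha * slope:
                accepted = True
                break
            alpha *= cfg.step_shrink
        if not accepted:
            converged = True
            iters -= 1
            break

        alpha_prev = alpha
        g_new = 2.0 * A.rmatvec(r_new).reshape(x.shape) + reg_grad(x_new)
        beta = max(0.0, float(np.sum(g_new * (g_new - g)) / np.sum(g * g)))
        d = -g_new + beta * d
        x, g, J, r = x_new, g_new, J_new, r_new
        trace.append(J)

    return ReconResult(
        ImageGrid(x, A.pixel_size),
        cost_trace=np.asarray(trace),
        iterations_run=iters,
        converged=converged,
    )


def param_search(
    A: SystemMatrix,
    y: Sinogram,
    reference: np.ndarray,
    lambdas: Sequence[float],
    cfg: CsConfig | None = None,
    error_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> tuple[float, dict[float, float]]:
    """Grid search over the TV weight minimizing reconstruction error
    against a reference image (exhaustive evaluation).

    Returns the best weight and the evaluated error surface.
    """
    if len(lambdas) == 0:
        raise ValueError("empty candidate grid")
    from .metrics import rrmse

    err = error_fn or rrmse
    base = cfg or CsConfig()
    surface: dict[float, float] = {}
    for lam in lambdas:
        run_cfg = _with_lambdas(base, lambda1=lam, lambda2=0.0)
        res = nlcg_reconstruct(A, y, run_cfg)
        surface[lam] = err(res.image.values, reference)
    best = min(surface, key=surface.get)
    return best, surface


def alternating_param_search(
    A: SystemMatrix,
    y: Sinogram,
    reference: np.ndarray,
    lambda1_grid: Sequence[float],
    lambda2_grid: Sequence[float],
    cfg: CsConfig | None = None,
    lambda2_init: float | None = None,
    max_rounds: int = 10,
    error_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> tuple[float, float, dict[tuple[float, float], float]]:
    """Alternating coordinate search over (lambda1, lambda2): optimize one
    weight with the other fixed, swap, and repeat until neither changes.
    """
    if len(lambda1_grid) == 0 or len(lambda2_grid) == 0:
        raise ValueError("empty candidate grid")
    from .metrics import rrmse

    err = error_fn or rrmse
    base = cfg or CsConfig()
    surface: dict[tuple[float, float], float] = {}

    def evaluate(l1: float, l2: float) -> float:
        key = (l1, l2)
        if key not in surface:
            res = nlcg_reconstruct(A, y, _with_lambdas(base, lambda1=l1, lambda2=l2))
            surface[key] = err(res.image.values, reference)
        return surface[key]

    l2 = lambda2_init if lambda2_init is not None else lambda2_grid[0]
    l1 = lambda1_grid[0]
    for _ in range(max_rounds):
        new_l1 = min(lambda1_grid, key=lambda c: evaluate(c, l2))
        new_l2 = min(lambda2_grid, key=lambda c: evaluate(new_l1, c))
        if new_l1 == l1 and new_l2 == l2:
            break
        l1, l2 = new_l1, new_l2
    return l1, l2, surface


def _with_lambdas(cfg: CsConfig, lambda1: float, lambda2: float) -> CsConfig:
    from dataclasses import replace

    return replace(cfg, lambda1=lambda1, lambda2=lambda2)
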