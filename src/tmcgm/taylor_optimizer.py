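"""Gauss–Newton optimization of the whitening coefficients.

The corrected series x̃⁽⁰⁾(α) is affine in the whitening vector α, so a
first-order Taylor expansion of the approximation vector F(α) around the
current iterate is exact up to rounding.  Each iteration builds a forward
finite-difference Jacobian A (step C_i = α_i / R with a small floor),
solves the linearized least-squares problem for the update η against the
deviation FD = G − F, clamps the new α into [0, 1], and monitors the
linearized residual Q = ‖FD − A·η‖².  On this affine objective the
iteration reaches the unconstrained optimum in one step; clamping
projects it into the box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gm11 import GM11Fit
from .markov_residual import CorrectionContext, corrected_series
from .series_io import ObservationSeries

__all__ = [
    "OptimizerConfig",
    "OptimizerResult",
    "objective_vector",
    "approx_vector",
    "fd_jacobian",
    "gauss_newton_step",
    "evaluate_q",
    "optimize_alpha",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Tuning knobs of the Gauss–Newton iteration.

    ``step_ratio`` is the step-length coefficient R dividing each α_i to
    form its finite-difference step (default 200); ``min_fd_step`` floors
    the step so α_i = 0 still perturbs.  Iteration stops when the
    linearized residual Q or the sup-norm of the update drops below
    ``tol``, or after ``max_iter`` rounds.
    """

    step_ratio: float = 200.0
    tol: float = 1e-8
    max_iter: int = 100
    alpha0: np.ndarray | None = None
    min_fd_step: float = 1e-4

    def __post_init__(self) -> None:
        if self.step_ratio <= 0 or self.tol <= 0 or self.min_fd_step <= 0:
            raise ValueError("step_ratio, tol and min_fd_step must be positive")
        if self.alpha0 is not None:
            a0 = np.asarray(self.alpha0, dtype=float)
            if np.any(a0 < 0) or np.any(a0 > 1):
                raise ValueError("alpha0 entries must lie in [0, 1]")
            object.__setattr__(self, "alpha0", a0)


@dataclass(frozen=True)
class OptimizerResult:
    alpha: np.ndarray
    q_trace: tuple[float, ...]
    iterations: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "q_trace": list(self.q_trace),
            "iterations": self.iterations,
            "converged": self.converged,
        }


def objective_vector(series: ObservationSeries) -> np.ndarray:
    """Target vector G: the observed series itself."""
    return series.values.astype(float, copy=True)


def approx_vector(fit: GM11Fit, ctx: CorrectionContext, alpha) -> np.ndarray:
    """Approximation vector F(α): the corrected series at a given α."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]^r")
    return corrected_series(fit, ctx, alpha=alpha)


def fd_jacobian(
    fit: GM11Fit, ctx: CorrectionContext, alpha, config: OptimizerConfig | None = None
) -> np.ndarray:
    """Forward finite-difference Jacobian of F with respect to α (n×r).

    Column i uses the step C_i = max(α_i / R, min_fd_step); the floor
    prevents a zero step at α_i = 0.  Steps never leave [0, 1] issues
    here because F is affine and evaluable for any real α internally.
    """
    config = config or OptimizerConfig()
    alpha = np.asarray(alpha, dtype=float)
    F0 = corrected_series(fit, ctx, alpha=alpha)
    A = np.empty((fit.n, alpha.size))
    for i in range(alpha.size):
        step = max(alpha[i] / config.step_ratio, config.min_fd_step)
        bumped = alpha.copy()
        bumped[i] += step
        A[:, i] = (corrected_series(fit, ctx, alpha=bumped) - F0) / step
    return A


def gauss_newton_step(A: np.ndarray, FD: np.ndarray, alpha) -> tuple[np.ndarray, np.ndarray]:
    """One update: solve A·η ≈ FD in least squares, clamp α + η to [0, 1].

    Rank-deficient systems (a state that never appears as a successor
    contributes a zero Jacobian column) fall back to the minimum-norm
    pseudo-inverse solution, leaving the unidentified coefficient at its
    current value as far as possible.
    """
    alpha = np.asarray(alpha, dtype=float)
    eta, _, rank, _ = np.linalg.lstsq(A, FD, rcond=None)
    if rank < A.shape[1]:
        logger.warning("rank-deficient Jacobian (rank %d < %d); minimum-norm update used", rank, A.shape[1])
    return np.clip(alpha + eta, 0.0, 1.0), eta


def evaluate_q(A: np.ndarray, FD: np.ndarray, eta: np.ndarray) -> float:
    """Evaluation function Q: squared norm of the linearized residual FD − A·η."""
    return float(np.sum((FD - A @ eta) ** 2))


def optimize_alpha(
    fit: GM11Fit, ctx: CorrectionContext, config: OptimizerConfig | None = None
) -> OptimizerResult:
    """Iterate Gauss–Newton steps from α = (0.5, …, 0.5) until convergence.

    Deterministic: identical inputs give identical traces.  Convergence
    is declared when Q ≤ tol or ‖η‖∞ ≤ tol; on the affine correction
    model this happens within a few iterations unless the optimum sits on
    the box boundary, where the undamped update may keep projecting.
    """
    config = config or OptimizerConfig()
    G = objective_vector(fit.source)
    r = ctx.partition.r
    alpha = (
        np.full(r, 0.5) if config.alpha0 is None else np.asarray(config.alpha0, dtype=float).copy()
    )
    if alpha.size != r:
        raise ValueError("alpha0 length must equal the state count r")
    q_trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        F = corrected_series(fit, ctx, alpha=alpha)
        FD = G - F
        A = fd_jacobian(fit, ctx, alpha, config)
        alpha_next, eta = gauss_newton_step(A, FD, alpha)
        Q = evaluate_q(A, FD, eta)
        if not np.isfinite(Q):
            raise FloatingPointError(f"non-finite evaluation function Q after trace {q_trace}")
        q_trace.append(Q)
        logger.debug("iter %d: Q=%.3e alpha=%s", iterations, Q, alpha_next)
        alpha = alpha_next
        if Q <= config.tol or float(np.max(np.abs(eta))) <= config.tol:
            converged = True
            break
    return OptimizerResult(
        alpha=alpha, q_trace=tuple(q_trace), iterations=iterations, converged=converged
    )
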