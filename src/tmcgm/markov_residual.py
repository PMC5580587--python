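"""Markov-chain correction of GM(1,1) residuals.

The signed in-sample residuals e(i) = x⁽⁰⁾(i) − x̂⁽⁰⁾(i) for points 2..n
are partitioned into ``r`` equal-width states spanning [min e, max e].
A first-order Markov chain over the state labels supplies one-step
transition probabilities; each state's interval [L_j, U_j] is a grey
number whitened to a point correction v_j = α_j·L_j + (1−α_j)·U_j.  The
corrected series adds the probability-weighted whitened correction to the
GM(1,1) value:

    x̃⁽⁰⁾(t+1) = x̂⁽⁰⁾(t+1) + Σ_i a_i(t)·v_i,
    a(t) = a(t−1)·P(1).

In-sample the previous state is observed, so a(t−1) is its hard indicator
propagated one step through P(1); beyond the sample the distribution
keeps propagating through P(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gm11 import GM11Fit, forecast_gm11

__all__ = [
    "StatePartition",
    "TransitionModel",
    "CorrectionContext",
    "DegeneratePartitionError",
    "partition_states",
    "estimate_transitions",
    "propagate",
    "whiten",
    "corrected_series",
    "forecast_corrected",
]


class DegeneratePartitionError(ValueError):
    """All residuals identical: equal-width states have zero width."""


@dataclass(frozen=True)
class StatePartition:
    """``r`` equal-width residual states with 1-based point labels.

    ``labels[k]`` is the state of the residual at point k+2 (points 2..n
    carry residuals; the anchor point has none).  Internal boundaries
    follow the half-open rule [L_j, U_j) with the last state closed, so a
    residual exactly on a shared bound belongs to the higher state.
    """

    r: int
    lower: np.ndarray
    upper: np.ndarray
    labels: np.ndarray

    def interval(self, state: int) -> tuple[float, float]:
        """Bounds (L, U) of a 1-based state."""
        return float(self.lower[state - 1]), float(self.upper[state - 1])

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "labels": self.labels.tolist(),
        }


@dataclass(frozen=True)
class TransitionModel:
    """m-step transition counts M_ij(m), totals M_i and row-stochastic P(m)."""

    step: int
    counts: np.ndarray
    totals: np.ndarray
    matrix: np.ndarray

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "counts": self.counts.tolist(),
            "totals": self.totals.tolist(),
            "matrix": self.matrix.tolist(),
        }


@dataclass
class CorrectionContext:
    """Everything needed to turn a GM(1,1) fit into a corrected series.

    ``alpha`` holds the whitening coefficients in [0,1]^r; ``probs`` is
    filled by :func:`corrected_series` with the propagated state
    distribution a(t) for each corrected in-sample point (points 3..n).
    """

    partition: StatePartition
    transitions: TransitionModel
    alpha: np.ndarray
    probs: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.size != self.partition.r:
            raise ValueError("alpha length must equal the state count r")
        if np.any(alpha < 0) or np.any(alpha > 1):
            raise ValueError("whitening coefficients must lie in [0, 1]")
        self.alpha = alpha


def partition_states(residuals, r: int) -> StatePartition:
    """Split residuals into ``r`` equal-width states over [min e, max e].

    ``residuals`` are the signed errors of points 2..n (the structural
    zero at the anchor is excluded by the caller).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 2:
        raise ValueError("need at least two residuals to partition")
    if r < 1:
        raise ValueError("state count r must be >= 1")
    lo, hi = float(residuals.min()), float(residuals.max())
    if hi <= lo:
        raise DegeneratePartitionError(
            "all residuals identical; equal-width states are degenerate "
            "(the fit is exact and needs no Markov correction)"
        )
    width = (hi - lo) / r
    j = np.arange(r, dtype=float)
    lower = lo + j * width
    upper = lo + (j + 1.0) * width
    labels = np.minimum(np.floor((residuals - lo) / width).astype(int), r - 1) + 1
    return StatePartition(r=r, lower=lower, upper=upper, labels=labels)


def estimate_transitions(labels, r: int, m: int = 1) -> TransitionModel:
    """Count m-step transitions and normalize rows to probabilities.

    ``totals[i]`` counts label-i occurrences that still have an m-step
    successor (the final m labels are excluded).  A state never observed
    with a successor gets the uninformative uniform row 1/r.
    """
    labels = np.asarray(labels, dtype=int)
    if m < 1:
        raise ValueError("step m must be >= 1")
    if m >= labels.size:
        raise ValueError(f"step m={m} needs more than {m} labels, got {labels.size}")
    if np.any(labels < 1) or np.any(labels > r):
        raise ValueError("labels must be 1-based states in 1..r")
    counts = np.zeros((r, r), dtype=int)
    np.add.at(counts, (labels[:-m] - 1, labels[m:] - 1), 1)
    totals = counts.sum(axis=1)
    matrix = np.full((r, r), 1.0 / r)
    occupied = totals > 0
    matrix[occupied] = counts[occupied] / totals[occupied, None]
    return TransitionModel(step=m, counts=counts, totals=totals, matrix=matrix)


def propagate(a0, P, steps: int = 1) -> np.ndarray:
    """Push a state distribution ``steps`` times through P: a ← a·P."""
    a = np.asarray(a0, dtype=float)
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or a.shape != (P.shape[0],):
        raise ValueError("dimension mismatch between distribution and transition matrix")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    for _ in range(steps):
        a = a @ P
    return a


def whiten(partition: StatePartition, alpha) -> np.ndarray:
    """Whitened corrections v_j = α_j·L_j + (1−α_j)·U_j, one per state."""
    alpha = np.asarray(alpha, dtype=float)
    return alpha * partition.lower + (1.0 - alpha) * partition.upper


def corrected_series(fit: GM11Fit, ctx: CorrectionContext, alpha=None) -> np.ndarray:
    """In-sample Markov-corrected series x̃⁽⁰⁾, same length as the fit.

    Point 1 is the uncorrected anchor and point 2, carrying the first
    labeled residual, has no predecessor state — both pass through
    unchanged.  From point 3 on, the observed state of the previous point
    is propagated one step through P(1) and the whitened corrections are
    averaged under that distribution.
    """
    alpha = ctx.alpha if alpha is None else np.asarray(alpha, dtype=float)
    v = whiten(ctx.partition, alpha)
    P = ctx.transitions.matrix
    labels = ctx.partition.labels
    out = fit.fitted.copy()
    probs = np.empty((max(fit.n - 2, 0), ctx.partition.r))
    for idx in range(2, fit.n):
        a_t = P[labels[idx - 2] - 1]  # indicator of state at point idx-1, one P(1) step
        probs[idx - 2] = a_t
        out[idx] = fit.fitted[idx] + a_t @ v
    ctx.probs = probs
    return out


def forecast_corrected(fit: GM11Fit, ctx: CorrectionContext, horizon: int) -> np.ndarray:
    """Corrected forecasts for points n+1 .. n+horizon.

    The state distribution starts as the indicator of the last in-sample
    residual state and keeps propagating through P(1), one step per
    forecast year.
    """
    base = forecast_gm11(fit, horizon)
    v = whiten(ctx.partition, ctx.alpha)
    a = np.zeros(ctx.partition.r)
    a[ctx.partition.labels[-1] - 1] = 1.0
    out = np.empty(horizon)
    for h in range(horizon):
        a = propagate(a, ctx.transitions.matrix)
        out[h] = base[h] + a @ v
    return out
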