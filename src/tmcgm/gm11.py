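"""The classical GM(1,1) grey forecasting model.

GM(1,1) smooths a short positive series x⁽⁰⁾ by the accumulated
generating operation (AGO) x⁽¹⁾ = cumsum(x⁽⁰⁾) and fits the whitenization
differential equation dx⁽¹⁾/dt + a·x⁽¹⁾ = b through its discrete form

    x⁽⁰⁾(j) + a·z⁽¹⁾(j) = b,      j = 2..n,

where z⁽¹⁾ is the mean (background) sequence of consecutive AGO values.
The developing coefficient ``a`` and grey action ``b`` are estimated by
least squares; restored values follow the closed form

    x̂⁽⁰⁾(i+1) = (x⁽⁰⁾(1) − b/a)(1 − eᵃ)e^{−a·i},   i ≥ 1,

with the first point anchored at the observation itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series_io import ObservationSeries

__all__ = ["GM11Fit", "ago", "mean_sequence", "fit_gm11", "restore_gm11", "forecast_gm11"]

# Below this magnitude of a, Eq-style restoration is an indeterminate 0/0
# and the analytic a -> 0 limit (constant level b) is used instead.
_A_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class GM11Fit:
    """A fitted GM(1,1) model.

    ``fitted`` holds the restored in-sample series x̂⁽⁰⁾ with
    ``fitted[0] == x⁽⁰⁾(1)`` (the anchor), and ``residuals`` the signed
    errors e(i) = x⁽⁰⁾(i) − x̂⁽⁰⁾(i), so ``residuals[0] == 0`` always.
    """

    a: float
    b: float
    x0_first: float
    fitted: np.ndarray
    residuals: np.ndarray
    source: ObservationSeries

    @property
    def n(self) -> int:
        return self.fitted.size

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "x0_first": self.x0_first,
            "fitted": self.fitted.tolist(),
            "residuals": self.residuals.tolist(),
        }


def ago(values) -> np.ndarray:
    """Accumulated generating operation: running cumulative sum."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("AGO of an empty sequence is undefined")
    return np.cumsum(values)


def mean_sequence(x1) -> np.ndarray:
    """Background sequence z⁽¹⁾(k) = ½[x⁽¹⁾(k−1) + x⁽¹⁾(k)], length n−1."""
    x1 = np.asarray(x1, dtype=float)
    if x1.size < 2:
        raise ValueError("mean sequence needs at least two cumulative values")
    return 0.5 * (x1[:-1] + x1[1:])


def fit_gm11(series: ObservationSeries) -> GM11Fit:
    """Estimate (a, b) by least squares on the grey difference equation.

    The design matrix has rows (−z⁽¹⁾(j), 1) against targets x⁽⁰⁾(j) for
    j = 2..n, solved by a stable factorization (equivalent to the normal
    equations (BᵀB)⁻¹BᵀY when B has full rank).
    """
    x0 = series.values
    z1 = mean_sequence(ago(x0))
    B = np.column_stack([-z1, np.ones_like(z1)])
    if np.linalg.matrix_rank(B) < 2:
        raise np.linalg.LinAlgError("singular grey design matrix: background sequence is constant")
    Y = x0[1:]
    (a, b), *_ = np.linalg.lstsq(B, Y, rcond=None)
    fit = GM11Fit(
        a=float(a),
        b=float(b),
        x0_first=float(x0[0]),
        fitted=np.empty(0),
        residuals=np.empty(0),
        source=series,
    )
    fitted = np.array([restore_gm11(fit, i) for i in range(series.n)])
    residuals = x0 - fitted
    residuals[0] = 0.0  # anchored by construction; kill rounding noise
    object.__setattr__(fit, "fitted", fitted)
    object.__setattr__(fit, "residuals", residuals)
    if not np.all(np.isfinite(fitted)):
        raise FloatingPointError("non-finite restored value (|a| too large for series length)")
    return fit


def restore_gm11(fit: GM11Fit, i: int) -> float:
    """Restored value x̂⁽⁰⁾(i+1); ``i = 0`` returns the anchor x⁽⁰⁾(1)."""
    if i < 0:
        raise ValueError("index must be >= 0")
    if i == 0:
        return fit.x0_first
    if abs(fit.a) < _A_ZERO_TOL:
        return fit.b
    with np.errstate(over="raise"):
        try:
            return float((fit.x0_first - fit.b / fit.a) * (1.0 - np.exp(fit.a)) * np.exp(-fit.a * i))
        except FloatingPointError as exc:
            raise FloatingPointError(f"overflow restoring point {i + 1} with a={fit.a:.4g}") from exc


def forecast_gm11(fit: GM11Fit, horizon: int) -> np.ndarray:
    """Out-of-sample continuation x̂⁽⁰⁾(n+1 .. n+horizon)."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    return np.array([restore_gm11(fit, fit.n - 1 + h) for h in range(1, horizon + 1)])
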