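"""End-to-end T-MCGM(1,1) runs and accuracy metrics.

``run_tmcgm`` chains the full method — GM(1,1) fit, residual-state
partition, one-step transition estimation, Gauss–Newton whitening
optimization, in-sample correction and out-of-sample forecasting — into a
single serializable report carrying MAPE/RMSE for both the plain and the
corrected model.  ``sweep_states`` repeats the run over several state
counts r and keeps the best in-sample fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .gm11 import GM11Fit, fit_gm11, forecast_gm11
from .markov_residual import (
    CorrectionContext,
    corrected_series,
    estimate_transitions,
    forecast_corrected,
    partition_states,
)
from .series_io import ObservationSeries
from .taylor_optimizer import OptimizerConfig, OptimizerResult, optimize_alpha

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "mape",
    "rmse",
    "run_tmcgm",
    "sweep_states",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of a full run.

    Metrics default to points 2..n (``mape_skip_anchor=True``): the first
    fitted point equals the first observation by construction, so its
    zero error is structural, not evidence of fit quality.
    """

    r: int = 3
    horizon: int = 7
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    mape_skip_anchor: bool = True
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("state count r must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")


@dataclass(frozen=True)
class RunReport:
    """Everything a run produced, JSON-serializable via :meth:`to_dict`."""

    series: ObservationSeries
    config: PipelineConfig
    fit: GM11Fit
    ctx: CorrectionContext
    optimizer: OptimizerResult
    corrected: np.ndarray
    forecast_years: tuple[int, ...]
    forecast_gm: np.ndarray
    forecast_tmcgm: np.ndarray
    metrics: dict

    def to_dict(self) -> dict:
        return {
            "series": {"name": self.series.name, "years": list(self.series.years),
                       "values": self.series.values.tolist()},
            "config": {"r": self.config.r, "horizon": self.config.horizon,
                       "mape_skip_anchor": self.config.mape_skip_anchor},
            "gm11": self.fit.to_dict(),
            "partition": self.ctx.partition.to_dict(),
            "transitions": self.ctx.transitions.to_dict(),
            "optimizer": self.optimizer.to_dict(),
            "corrected": self.corrected.tolist(),
            "forecast": {"years": list(self.forecast_years),
                         "gm11": self.forecast_gm.tolist(),
                         "tmcgm": self.forecast_tmcgm.tolist()},
            "metrics": self.metrics,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        return json.dumps(self.to_dict(), **kwargs)


def mape(actual, predicted, skip_first: bool = True) -> float:
    """Mean absolute percentage error, in percent: (100/n)·Σ|aᵢ−pᵢ|/aᵢ."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if skip_first:
        actual, predicted = actual[1:], predicted[1:]
    if actual.size == 0:
        raise ValueError("no points left to score")
    if np.any(actual == 0):
        raise ValueError("MAPE undefined for zero actual values")
    return float(100.0 * np.mean(np.abs(actual - predicted) / np.abs(actual)))


def rmse(actual, predicted, skip_first: bool = True) -> float:
    """Root mean square error: √(Σ(aᵢ−pᵢ)²/n)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if skip_first:
        actual, predicted = actual[1:], predicted[1:]
    if actual.size == 0:
        raise ValueError("no points left to score")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def _stage(name: str):
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Guard()


def run_tmcgm(series: ObservationSeries, config: PipelineConfig | None = None) -> RunReport:
    """Run the full corrected-grey pipeline on one series.

    Fully deterministic: no random number generator is involved at any
    stage.
    """
    config = config or PipelineConfig()
    with _stage("gm11 fit"):
        fit = fit_gm11(series)
    with _stage("state partition"):
        partition = partition_states(fit.residuals[1:], config.r)
    with _stage("transition estimation"):
        transitions = estimate_transitions(partition.labels, config.r, m=1)
    ctx = CorrectionContext(
        partition=partition, transitions=transitions, alpha=np.full(config.r, 0.5)
    )
    with _stage("whitening optimization"):
        opt = optimize_alpha(fit, ctx, config.optimizer)
    ctx.alpha = opt.alpha
    with _stage("correction"):
        corrected = corrected_series(fit, ctx)
    with _stage("forecast"):
        fc_gm = forecast_gm11(fit, config.horizon)
        fc_tm = (
            forecast_corrected(fit, ctx, config.horizon)
            if config.horizon > 0
            else np.empty(0)
        )
    skip = config.mape_skip_anchor
    metrics = {
        "GM11": {
            "mape": mape(series.values, fit.fitted, skip),
            "rmse": rmse(series.values, fit.fitted, skip),
        },
        "TMCGM11": {
            "mape": mape(series.values, corrected, skip),
            "rmse": rmse(series.values, corrected, skip),
        },
    }
    last_year = series.years[-1]
    return RunReport(
        series=series,
        config=config,
        fit=fit,
        ctx=ctx,
        optimizer=opt,
        corrected=corrected,
        forecast_years=tuple(range(last_year + 1, last_year + 1 + config.horizon)),
        forecast_gm=fc_gm,
        forecast_tmcgm=fc_tm,
        metrics=metrics,
    )


def sweep_states(
    series: ObservationSeries,
    r_values=(3, 4, 5),
    config: PipelineConfig | None = None,
) -> tuple[RunReport, dict[int, RunReport]]:
    """Run the pipeline for each state count and pick the best one.

    Selection minimizes the corrected in-sample MAPE; ties go to the
    smallest r (fewer states, fewer free coefficients).  Returns the best
    report and the full map r → report.
    """
    base = config or PipelineConfig()
    reports: dict[int, RunReport] = {}
    for r in r_values:
        cfg = PipelineConfig(
            r=r,
            horizon=base.horizon,
            optimizer=base.optimizer,
            mape_skip_anchor=base.mape_skip_anchor,
            output_path=base.output_path,
        )
        reports[r] = run_tmcgm(series, cfg)
    best_r = min(reports, key=lambda r: (reports[r].metrics["TMCGM11"]["mape"], r))
    return reports[best_r], reports
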