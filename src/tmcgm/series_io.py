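"""Time-series input/output and synthetic grey-series generation.

The raw input of a grey GM(1,1) analysis is a short annual series of
strictly positive rates, here two-week hospitalization rates in per mille
(‰).  This module validates and loads such series from CSV/JSON, ships a
small bundled dataset of urban hospitalization rates for three chronic
diseases (diabetes ``DD``, heart disease ``HD``, cerebrovascular disease
``CD``, 2006–2015), and generates synthetic series with known grey
parameters for testing parameter recovery and residual-state recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservationSeries",
    "SyntheticSpec",
    "SeriesValidationError",
    "SeriesInputError",
    "GenerationError",
    "load_series",
    "write_series",
    "load_hospitalization_rates",
    "bundled_data_path",
    "generate_grey_series",
]

_BUNDLED_NAME = "twoweek_hospitalization_rates.csv"


class SeriesValidationError(ValueError):
    """A series violates the GM(1,1) preconditions (positivity, length, years)."""


class SeriesInputError(ValueError):
    """A file or column could not be read as a series."""


class GenerationError(ValueError):
    """Synthetic-series parameters produce an invalid (non-positive) series."""


@dataclass(frozen=True)
class ObservationSeries:
    """An annual positive-valued series x⁽⁰⁾, the raw GM(1,1) input.

    Parameters
    ----------
    name
        Column label, e.g. a disease code.
    years
        Consecutive integer years, strictly increasing by one.
    values
        Strictly positive rates (‰), one per year.  At least four points
        are required: the least-squares fit uses points 2..n and needs
        more equations than the two grey parameters.
    """

    name: str
    years: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(years) != values.size:
            raise SeriesValidationError(
                f"series {self.name!r}: years and values must be equal-length 1-d sequences"
            )
        if values.size < 4:
            raise SeriesValidationError(
                f"series {self.name!r}: need at least 4 observations, got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise SeriesValidationError(f"series {self.name!r}: non-finite value present")
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise SeriesValidationError(
                f"series {self.name!r}: non-positive value {values[bad[0]]!r} "
                f"at year {years[bad[0]]} (grey modelling requires x(0)(i) > 0)"
            )
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise SeriesValidationError(
                f"series {self.name!r}: years must increase consecutively by 1"
            )

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for a synthetic grey series with optional Markov noise.

    ``a_true`` (developing coefficient) and ``b_true`` (grey action) define
    the noiseless branch through the grey difference equation
    ``x⁽⁰⁾(j) + a·z⁽¹⁾(j) = b``; ``noise_states`` adds a Markov-switching
    additive offset drawn from ``(weight, offset)`` pairs.  When
    ``transition`` is omitted, every row of the switching chain equals the
    normalized weights (i.i.d. switching); pass an explicit row-stochastic
    matrix for correlated regimes, e.g. ``[[0, 1], [1, 0]]`` for strict
    alternation.
    """

    a_true: float
    b_true: float
    x1: float
    n: int
    noise_states: tuple[tuple[float, float], ...] = ()
    transition: tuple[tuple[float, ...], ...] | None = None
    seed: int = 0
    start_year: int = 2006
    name: str = "synthetic"


def _series_from_frame(frame: pd.DataFrame, column: str, path: str | Path) -> ObservationSeries:
    if "year" not in frame.columns:
        raise SeriesInputError(f"{path}: required 'year' column missing")
    if column not in frame.columns:
        raise SeriesInputError(
            f"{path}: column {column!r} not found (available: "
            f"{', '.join(c for c in frame.columns if c != 'year')})"
        )
    values = pd.to_numeric(frame[column], errors="coerce")
    if values.isna().any():
        bad_year = frame.loc[values.isna(), "year"].iloc[0]
        raise SeriesInputError(f"{path}: column {column!r} has a non-numeric value at year {bad_year}")
    return ObservationSeries(
        name=column,
        years=tuple(int(y) for y in frame["year"]),
        values=values.to_numpy(dtype=float),
    )


def load_series(path: str | Path, column: str) -> ObservationSeries:
    """Load one named series from a CSV (``year,<col>,...``) or JSON file.

    JSON mirrors the CSV schema as a mapping of column name to list:
    ``{"year": [...], "<name>": [...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise SeriesInputError(f"input file not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        if not isinstance(payload, dict):
            raise SeriesInputError(f"{path}: JSON input must be an object of columns")
        frame = pd.DataFrame(payload)
    else:
        frame = pd.read_csv(path)
    return _series_from_frame(frame, column, path)


def write_series(series: ObservationSeries, path: str | Path) -> None:
    """Write a series to CSV or JSON (by extension); round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"year": list(series.years), series.name: [float(v) for v in series.values]}
        path.write_text(json.dumps(payload, indent=1))
    else:
        frame = pd.DataFrame({"year": series.years, series.name: series.values})
        frame.to_csv(path, index=False)


def bundled_data_path() -> Path:
    """Filesystem path of the bundled hospitalization-rate table."""
    return Path(str(resources.files("tmcgm").joinpath("data", _BUNDLED_NAME)))


def load_hospitalization_rates(column: str) -> ObservationSeries:
    """Load one disease series (``DD``, ``HD`` or ``CD``) from the bundled
    2006–2015 urban two-week hospitalization-rate table (‰)."""
    return load_series(bundled_data_path(), column)


def _grey_recurrence(a: float, b: float, x1: float, n: int) -> np.ndarray:
    # x(0)(j) = (b - a*x1(j-1)) / (1 + a/2): the unique continuation for
    # which x(0)(j) + a*z1(j) = b holds exactly with z1 the running mean
    # of the cumulative series.
    if abs(1.0 + a / 2.0) < 1e-12:
        raise GenerationError("developing coefficient a = -2 makes the recurrence singular")
    out = np.empty(n)
    out[0] = x1
    cum = x1
    for j in range(1, n):
        out[j] = (b - a * cum) / (1.0 + a / 2.0)
        cum += out[j]
    return out


def generate_grey_series(spec: SyntheticSpec) -> ObservationSeries:
    """Generate a synthetic series from known grey parameters.

    The noiseless branch satisfies the grey difference equation exactly at
    every point, so the GM(1,1) least-squares fit recovers
    ``(a_true, b_true)`` to machine precision.  With ``noise_states`` set,
    a seeded Markov chain over the states adds its offset to each point;
    the chain starts from a uniformly drawn initial state (an
    uninformative stand-in for the stationary distribution, which depends
    on the supplied transition matrix).  Runs are bit-reproducible for a
    fixed seed.
    """
    if spec.n < 4:
        raise GenerationError("need n >= 4 points")
    values = _grey_recurrence(spec.a_true, spec.b_true, spec.x1, spec.n)
    if spec.noise_states:
        rng = np.random.default_rng(spec.seed)
        weights = np.array([w for w, _ in spec.noise_states], dtype=float)
        offsets = np.array([o for _, o in spec.noise_states], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise GenerationError("noise-state weights must be non-negative and not all zero")
        k = weights.size
        if spec.transition is not None:
            P = np.asarray(spec.transition, dtype=float)
            if P.shape != (k, k) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
                raise GenerationError("transition must be a row-stochastic matrix over the noise states")
        else:
            P = np.tile(weights / weights.sum(), (k, 1))
        state = rng.integers(k)
        for j in range(spec.n):
            values[j] += offsets[state]
            state = rng.choice(k, p=P[state])
    bad = np.nonzero(values <= 0)[0]
    if bad.size:
        raise GenerationError(
            f"parameters produce non-positive value {values[bad[0]]:.6g} at index {bad[0]}"
        )
    return ObservationSeries(
        name=spec.name,
        years=tuple(range(spec.start_year, spec.start_year + spec.n)),
        values=values,
    )
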