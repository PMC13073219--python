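"""Strategy comparison statistics.

Covers the four analysis stages of a simulation run: descriptive summaries
per strategy (mean, SD, percentiles, threshold coverage, fire-first
fraction), the paired t-test between strategies, the exploratory
fire-turnout sweep locating the turnout beyond which the dual-dispatch
advantage is no longer statistically evident, and the Gaussian
identity-link GLM of response time on population density, strategy and
their interaction.

Both strategies are evaluated on the same simulated events, so the design
is intrinsically paired and the paired t-test is the default; an unpaired
Welch variant is available behind ``kind="welch"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .dispatch import ResponseRecord, TurnoutConfig, build_records
from .errors import FitError, StatsError
from .events import Event
from .geography import RoadNetwork, Service, StationSet
from .routing import best_travel_times

__all__ = [
    "Strategy",
    "StrategySummary",
    "ComparisonResult",
    "SweepResult",
    "GlmFit",
    "summarize",
    "compare_strategies",
    "turnout_sweep",
    "fit_density_glm",
    "predict_response",
]


class Strategy(str, Enum):
    EMS_ONLY = "EMS_ONLY"
    DUAL = "DUAL"


def _responses(records: Sequence[ResponseRecord], strategy: Strategy) -> np.ndarray:
    field_name = "ems_response_min" if strategy is Strategy.EMS_ONLY else "dual_response_min"
    return np.array([getattr(r, field_name) for r in records], dtype=float)


@dataclass(frozen=True)
class StrategySummary:
    strategy: Strategy
    n: int
    mean_min: float
    sd_min: float  # sample SD, n-1 denominator
    percentiles: dict[float, float]  # linear-interpolated
    frac_within: dict[float, float]  # response <= threshold, inclusive
    frac_fire_first: float | None = None  # DUAL only


@dataclass(frozen=True)
class ComparisonResult:
    mean_difference_min: float  # mean(ems_response - dual_response)
    t_statistic: float
    p_value: float
    test_kind: str  # "paired" | "welch"


@dataclass(frozen=True)
class SweepPoint:
    fire_turnout_min: float
    summary_ems: StrategySummary
    summary_dual: StrategySummary
    comparison: ComparisonResult


@dataclass(frozen=True)
class SweepResult:
    turnout_grid: tuple[float, ...]
    alpha: float
    points: tuple[SweepPoint, ...]
    threshold_turnout: float | None  # smallest grid value with p >= alpha


@dataclass(frozen=True)
class GlmFit:
    """Gaussian identity-link fit of response ~ density * strategy.

    Design columns: intercept, density (inhabitants/km^2), strategy
    indicator (1 = dual dispatch), density x strategy.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n_obs: int

    COLUMNS = ("intercept", "density", "strategy", "interaction")


DEFAULT_PERCENTILES = (10.0, 25.0, 50.0, 75.0, 90.0)


def summarize(
    records: Sequence[ResponseRecord],
    strategy: Strategy,
    thresholds: Sequence[float] = (10.0,),
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> StrategySummary:
    """Descriptive summary of one strategy's response-time distribution."""
    if len(records) == 0:
        raise StatsError("cannot summarise empty records")
    x = _responses(records, strategy)
    frac_fire = None
    if strategy is Strategy.DUAL:
        frac_fire = float(
            np.mean([r.first_arriver is Service.FIRE for r in records])
        )
    return StrategySummary(
        strategy=strategy,
        n=len(records),
        mean_min=float(np.mean(x)),
        sd_min=float(np.std(x, ddof=1)) if len(records) > 1 else 0.0,
        percentiles={
            float(p): float(np.percentile(x, p, method="linear")) for p in percentiles
        },
        frac_within={float(t): float(np.mean(x <= t)) for t in thresholds},
        frac_fire_first=frac_fire,
    )


def compare_strategies(
    records: Sequence[ResponseRecord], kind: str = "paired"
) -> ComparisonResult:
    """Two-sided t-test of EMS-only vs dual-dispatch response times.

    With every paired difference exactly zero (the strategies coincide) the
    test degenerates to t = 0, p = 1.
    """
    if len(records) < 2:
        raise StatsError("need at least 2 records for a t-test")
    ems = _responses(records, Strategy.EMS_ONLY)
    dual = _responses(records, Strategy.DUAL)
    diff = ems - dual
    if kind == "paired":
        if np.all(diff == 0.0):
            return ComparisonResult(0.0, 0.0, 1.0, "paired")
        t, p = sps.ttest_rel(ems, dual)
    elif kind == "welch":
        if np.all(diff == 0.0) and np.std(ems) == np.std(dual):
            return ComparisonResult(0.0, 0.0, 1.0, "welch")
        t, p = sps.ttest_ind(ems, dual, equal_var=False)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return ComparisonResult(
        mean_difference_min=float(np.mean(diff)),
        t_statistic=float(t),
        p_value=float(p),
        test_kind=kind,
    )


def sweep_from_travel(
    events: Sequence[Event],
    ems_travel: np.ndarray,
    fire_travel: np.ndarray,
    turnout_grid: Sequence[float],
    alpha: float = 0.05,
    ems_turnout_min: float = 2.0,
    thresholds: Sequence[float] = (10.0,),
) -> SweepResult:
    """Fire-turnout sweep on cached travel times (routing is turnout-free)."""
    grid = [float(g) for g in turnout_grid]
    if not grid or sorted(grid) != grid:
        raise StatsError("turnout grid must be non-empty and sorted ascending")
    points = []
    threshold = None
    for g in grid:
        turnout = TurnoutConfig(ems_turnout_min=ems_turnout_min, fire_turnout_min=g)
        records = build_records(events, ems_travel, fire_travel, turnout)
        comp = compare_strategies(records)
        points.append(
            SweepPoint(
                fire_turnout_min=g,
                summary_ems=summarize(records, Strategy.EMS_ONLY, thresholds),
                summary_dual=summarize(records, Strategy.DUAL, thresholds),
                comparison=comp,
            )
        )
        if threshold is None and comp.p_value >= alpha:
            threshold = g
    return SweepResult(
        turnout_grid=tuple(grid),
        alpha=alpha,
        points=tuple(points),
        threshold_turnout=threshold,
    )


def turnout_sweep(
    events: Sequence[Event],
    stations: StationSet,
    network: RoadNetwork,
    turnout_grid: Sequence[float],
    alpha: float = 0.05,
    ems_turnout_min: float = 2.0,
    k: int | str = 10,
) -> SweepResult:
    """Re-run the strategy comparison across a grid of fire turnout times.

    Travel times are computed once and reused: only the turnout component
    changes along the grid. ``threshold_turnout`` is the smallest grid value
    at which the paired test is no longer significant at ``alpha``, or None
    if the difference persists across the whole grid.
    """
    ems = best_travel_times(events, stations, network, Service.EMS, k)
    fire = best_travel_times(events, stations, network, Service.FIRE, k)
    return sweep_from_travel(
        events,
        np.array([r.best_travel_min for r in ems]),
        np.array([r.best_travel_min for r in fire]),
        turnout_grid,
        alpha=alpha,
        ems_turnout_min=ems_turnout_min,
    )


def _long_design(records: Sequence[ResponseRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Long-format design: two rows per event (EMS-only, dual)."""
    density = np.array([r.local_density for r in records], dtype=float)
    ems = _responses(records, Strategy.EMS_ONLY)
    dual = _responses(records, Strategy.DUAL)
    d = np.concatenate([density, density])
    s = np.concatenate([np.zeros_like(density), np.ones_like(density)])
    y = np.concatenate([ems, dual])
    X = np.column_stack([np.ones_like(d), d, s, d * s])
    return X, y


def fit_density_glm(records: Sequence[ResponseRecord]) -> GlmFit:
    """Gaussian GLM of response time on density, strategy and interaction.

    The density covariate is the raw raster-cell density at the event in
    inhabitants/km^2 (untransformed). R^2 is 1 - RSS/TSS on the long-format
    observations.
    """
    if len(records) < 2:
        raise StatsError("need at least 2 events to fit the model")
    X, y = _long_design(records)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending column for the caller
        if np.ptp(X[:, 1]) == 0:
            raise FitError("design is rank-deficient: 'density' is constant")
        if np.ptp(X[:, 2]) == 0:
            raise FitError("design is rank-deficient: 'strategy' is constant")
        raise FitError("design is rank-deficient: 'interaction' is collinear")
    fit = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
    resid = y - fit.fittedvalues
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    cols = GlmFit.COLUMNS
    return GlmFit(
        coefficients=dict(zip(cols, map(float, fit.params))),
        standard_errors=dict(zip(cols, map(float, fit.bse))),
        p_values=dict(zip(cols, map(float, fit.pvalues))),
        r_squared=1.0 - rss / tss if tss > 0 else 0.0,
        n_obs=int(len(y)),
    )


def predict_response(glm: GlmFit, density: float, strategy: Strategy | int) -> float:
    """Model-predicted response time for a density and strategy.

    ``strategy`` accepts the enum or the 0/1 indicator (1 = dual dispatch).
    """
    if not isinstance(glm, GlmFit):
        raise StatsError("predict_response requires a fitted model")
    s = (
        float(strategy)
        if isinstance(strategy, (int, float))
        else (1.0 if strategy is Strategy.DUAL else 0.0)
    )
    b = glm.coefficients
    return (
        b["intercept"]
        + b["density"] * density
        + b["strategy"] * s
        + b["interaction"] * density * s
    )
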