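"""NDVI compositing, drought-excluded baselines and anomaly quantification.

16-day NDVI composites are reduced to monthly values by maximum-value
compositing (MVC), which suppresses cloud-depressed observations.  Baselines
are per-calendar-month multiyear means computed with drought months (months
inside identified drought events) excluded, so the reference describes
non-drought conditions.  Anomalies are observed − baseline (negative = below
normal) with a percent form relative to the baseline; the same machinery
serves NDVI and the gridded hydrothermal variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import SeasonWindow
from .rasters import GridSpec, MonthlyStack

__all__ = [
    "Climatology",
    "AnomalyResult",
    "mvc_monthly",
    "baseline_climatology",
    "anomaly",
    "monthly_anomalies",
    "seasonal_anomaly",
    "minimum_shift",
]

#: below this absolute baseline, percent anomalies are reported undefined
NDVI_EPS = 0.01


@dataclass
class Climatology:
    """12 per-calendar-month baseline layers (January first) plus, per layer,
    the cellwise count of contributing (non-drought, non-missing) years."""

    baseline: np.ndarray      # (12, rows, cols)
    counts: np.ndarray        # (12, rows, cols) contributing years
    grid: GridSpec
    excluded_months: pd.PeriodIndex

    def layer(self, calendar_month: int) -> np.ndarray:
        return self.baseline[calendar_month - 1]


@dataclass
class AnomalyResult:
    """Absolute (observed − baseline) and percent (100·abs/baseline) anomalies.

    Negative = below baseline.  Percent is NaN where |baseline| < eps.
    Arrays for gridded scopes, scalars for regional/seasonal summaries.
    """

    absolute: np.ndarray | float
    percent: np.ndarray | float
    scope: str = ""
    stratum: str | None = None


def mvc_monthly(
    composites,
    dates,
    grid: GridSpec,
    name: str = "ndvi",
    valid_range: tuple[float, float] | None = (-1.0, 1.0),
) -> MonthlyStack:
    """Maximum-value composite: per cell, the max over a month's composites.

    A composite belongs to the month containing its start date.  Missing
    composite cells are ignored; a cell missing in all of a month's composites
    is missing.  Values outside ``valid_range`` are flagged invalid (NaN).
    """
    if len(composites) != len(dates):
        raise ValueError("composites and dates length mismatch")
    if len(composites) == 0:
        raise ValueError("no composites supplied")
    by_month: dict[pd.Period, list[np.ndarray]] = {}
    for arr, date in zip(composites, dates):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != grid.shape:
            raise ValueError(f"composite shape {arr.shape} != grid {grid.shape}")
        if valid_range is not None:
            arr = np.where(
                (arr < valid_range[0]) | (arr > valid_range[1]), np.nan, arr
            )
        per = pd.Period(pd.Timestamp(date), freq="M")
        by_month.setdefault(per, []).append(arr)

    months = pd.period_range(min(by_month), max(by_month), freq="M")
    layers = np.full((len(months), *grid.shape), np.nan)
    for i, per in enumerate(months):
        stack = by_month.get(per)
        if not stack:
            warnings.warn(f"no composites for month {per}; missing layer")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            layers[i] = np.nanmax(np.stack(stack), axis=0)
    return MonthlyStack(layers, months, grid, name=name)


def baseline_climatology(
    stack: MonthlyStack,
    drought_month_mask: pd.Series | None = None,
    fallback_all_years: bool = False,
) -> Climatology:
    """Per-calendar-month multiyear mean with drought months excluded.

    ``drought_month_mask`` is a boolean series over (a superset of) the stack's
    months; True months are excluded from the baseline.  Cells with no
    contributing year are missing unless ``fallback_all_years`` re-computes
    them from the unmasked mean.
    """
    if drought_month_mask is None:
        excl = pd.Series(False, index=stack.months)
    else:
        excl = drought_month_mask.reindex(stack.months, fill_value=False).astype(bool)

    baseline = np.full((12, *stack.grid.shape), np.nan)
    counts = np.zeros((12, *stack.grid.shape), dtype=int)
    month_of = stack.months.month.values
    excl_arr = excl.to_numpy()
    for m in range(1, 13):
        present = month_of == m
        if not present.any():
            continue
        sel = present & ~excl_arr
        if not sel.any():
            warnings.warn(f"all years of calendar month {m} are drought-masked")
            if fallback_all_years:
                sel = month_of == m
            else:
                continue
        layers = stack.values[sel]
        counts[m - 1] = np.sum(~np.isnan(layers), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            baseline[m - 1] = np.nanmean(layers, axis=0)
    return Climatology(
        baseline=baseline,
        counts=counts,
        grid=stack.grid,
        excluded_months=stack.months[excl_arr],
    )


def anomaly(observed, baseline, eps: float = NDVI_EPS, scope: str = "",
            stratum: str | None = None) -> AnomalyResult:
    """Absolute and percent deviation of ``observed`` from ``baseline``.

    Percent is undefined (NaN) where |baseline| < eps; the absolute anomaly is
    still reported there.
    """
    obs = np.asarray(observed, dtype=float)
    base = np.asarray(baseline, dtype=float)
    if obs.shape != base.shape:
        raise ValueError(f"observed shape {obs.shape} != baseline {base.shape}")
    absolute = obs - base
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(np.abs(base) >= eps, 100.0 * absolute / base, np.nan)
    if obs.ndim == 0:
        return AnomalyResult(float(absolute), float(percent), scope, stratum)
    return AnomalyResult(absolute, percent, scope, stratum)


def monthly_anomalies(
    stack: MonthlyStack, climatology: Climatology, eps: float = NDVI_EPS
) -> tuple[MonthlyStack, MonthlyStack]:
    """Cellwise monthly absolute and percent anomaly stacks."""
    month_of = stack.months.month.values
    base = climatology.baseline[month_of - 1]
    absolute = stack.values - base
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(np.abs(base) >= eps, 100.0 * absolute / base, np.nan)
    return (
        MonthlyStack(absolute, stack.months, stack.grid,
                     name=f"{stack.name}_anom", units=stack.units),
        MonthlyStack(percent, stack.months, stack.grid,
                     name=f"{stack.name}_anom_pct", units="%"),
    )


def seasonal_anomaly(
    monthly_absolute: pd.Series,
    monthly_baseline: pd.Series,
    window: SeasonWindow,
    eps: float = NDVI_EPS,
) -> AnomalyResult:
    """Season-scope anomaly: mean of member-month absolute anomalies, with the
    percent form taken against the mean seasonal baseline."""
    months = window.months
    abs_vals = monthly_absolute.reindex(months)
    base_vals = monthly_baseline.reindex(months)
    if abs_vals.isna().any() or base_vals.isna().any():
        warnings.warn(f"{window.season} {window.year}: missing member month")
        return AnomalyResult(float("nan"), float("nan"),
                             scope=f"{window.season}-{window.year}")
    mean_abs = float(abs_vals.mean())
    mean_base = float(base_vals.mean())
    pct = 100.0 * mean_abs / mean_base if abs(mean_base) >= eps else float("nan")
    return AnomalyResult(mean_abs, pct, scope=f"{window.season}-{window.year}")


def minimum_shift(observed_12: pd.Series | np.ndarray,
                  baseline_12: pd.Series | np.ndarray) -> int:
    """Signed shift (months) of the observed annual minimum relative to the
    baseline minimum over the same 12-month window.

    Positive = the observed minimum occurs later (e.g. a baseline January
    minimum delayed to March gives +2).  Ties break toward the earliest month,
    with a warning.
    """
    obs = np.asarray(observed_12, dtype=float)
    base = np.asarray(baseline_12, dtype=float)
    if obs.shape != (12,) or base.shape != (12,):
        raise ValueError("both inputs must cover exactly 12 months")
    if np.isnan(obs).any() or np.isnan(base).any():
        raise ValueError("minimum_shift requires complete 12-month curves")
    for name, arr in (("observed", obs), ("baseline", base)):
        if (arr == arr.min()).sum() > 1:
            warnings.warn(f"tied {name} minimum; earliest month used")
    return int(np.argmin(obs) - np.argmin(base))
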