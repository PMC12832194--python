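"""Run-theory drought event identification on a monthly SPEI series.

A drought month is one with SPEI-6 at or below −1.0.  Events are maximal runs
of drought months, with runs separated by at most ``merge_gap`` non-drought
months pooled into a single event (gap months count toward its duration), and
pooled runs shorter than ``min_duration`` months discarded.  Event severity is
the class of the peak (minimum) SPEI within the event.

Seasons follow the meteorological convention: spring Mar–May, summer Jun–Aug,
autumn Sep–Nov, winter Dec–Feb, with the winter of year Y spanning Dec Y to
Feb Y+1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spei import SeverityClass, classify_severity

__all__ = [
    "DroughtEvent",
    "SeasonWindow",
    "SEASON_MONTHS",
    "drought_months",
    "identify_events",
    "seasonal_mean_spei",
    "event_mask",
    "events_to_frame",
]

DEFAULT_THRESHOLD = -1.0

SEASON_MONTHS: dict[str, tuple[int, int, int]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


@dataclass(frozen=True)
class SeasonWindow:
    """A labelled meteorological season of a given year.

    Winter of year Y comprises December Y, January Y+1 and February Y+1.
    """

    season: str
    year: int

    def __post_init__(self) -> None:
        if self.season not in SEASON_MONTHS:
            raise ValueError(f"unknown season {self.season!r}")

    @property
    def months(self) -> pd.PeriodIndex:
        out = []
        for m in SEASON_MONTHS[self.season]:
            y = self.year + 1 if (self.season == "winter" and m != 12) else self.year
            out.append(pd.Period(year=y, month=m, freq="M"))
        return pd.PeriodIndex(out, freq="M")


@dataclass
class DroughtEvent:
    """A pooled run-theory event with per-month severity attribution."""

    onset: pd.Period
    termination: pd.Period
    duration: int
    peak_spei: float
    event_class: SeverityClass
    month_classes: dict[pd.Period, SeverityClass]

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.onset, self.termination, freq="M")


def drought_months(
    spei: pd.Series, threshold: float = DEFAULT_THRESHOLD
) -> pd.Series:
    """Boolean mask: True iff SPEI <= threshold.  Undefined months are False."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = (spei <= threshold) & spei.notna()
    mask.name = "drought"
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of maximal True runs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def identify_events(
    spei: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    min_duration: int = 2,
    merge_gap: int = 1,
) -> list[DroughtEvent]:
    """Extract drought events from a monthly SPEI series by run theory.

    Runs of sub-threshold months separated by at most ``merge_gap`` non-drought
    months are merged (the gap months are counted inside the merged event);
    merged events shorter than ``min_duration`` months are discarded.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    if len(spei) == 0:
        return []
    mask = drought_months(spei, threshold).to_numpy()
    runs = _runs(mask)

    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    events = []
    for start, stop in merged:
        if stop - start + 1 < min_duration:
            continue
        window = spei.iloc[start : stop + 1]
        peak = float(window.min())
        month_classes = {
            per: classify_severity(v)
            for per, v in window.items()
            if np.isfinite(v)
        }
        events.append(
            DroughtEvent(
                onset=spei.index[start],
                termination=spei.index[stop],
                duration=stop - start + 1,
                peak_spei=peak,
                event_class=classify_severity(peak),
                month_classes=month_classes,
            )
        )
    return events


def seasonal_mean_spei(spei: pd.Series, window: SeasonWindow) -> float:
    """Arithmetic mean SPEI over the season's three member months.

    Returns NaN with a warning if any member month is missing or undefined.
    """
    months = window.months
    if not months.isin(spei.index).all() or spei.reindex(months).isna().any():
        warnings.warn(
            f"{window.season} {window.year}: member month missing or undefined"
        )
        return float("nan")
    return float(spei.reindex(months).mean())


def event_mask(events: list[DroughtEvent], index: pd.PeriodIndex) -> pd.Series:
    """Boolean series over ``index``, True on every month inside any event
    (merged gap months included)."""
    mask = pd.Series(False, index=index, name="event_month")
    for ev in events:
        mask[mask.index.isin(ev.months)] = True
    return mask


def events_to_frame(events: list[DroughtEvent]) -> pd.DataFrame:
    """Tidy event table (one row per event)."""
    return pd.DataFrame(
        [
            {
                "event_id": i + 1,
                "onset": str(ev.onset),
                "termination": str(ev.termination),
                "duration_months": ev.duration,
                "peak_spei": ev.peak_spei,
                "event_class": str(ev.event_class),
            }
            for i, ev in enumerate(events)
        ]
    )
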