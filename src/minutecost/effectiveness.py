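"""Cumulative MVPA gain from repeated-measure weekly means.

The trial measures mean weekly MVPA minutes at a few study weeks
(baseline, 26, 52).  Between measurements the weekly rate is assumed to
change linearly, so the cumulative per-person gain over a window is the
trapezoidal integral, over weeks, of the interpolated weekly minutes
minus the baseline weekly minutes.  For a single segment this reduces
to (change in mean)/2 x weeks.

Convention: 6 months = 26 weeks, so a month is 26/6 weeks.  This is the
convention under which the published gain totals (e.g. 1362.4 minutes
over the first 26 weeks) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "WEEKS_PER_MONTH",
    "MEASURES",
    "OutcomeTimepoint",
    "OutcomeSeries",
    "EffectivenessSummary",
    "interpolate_weekly_minutes",
    "cumulative_gain",
    "weeks_to_months",
    "gain_per_month",
]

#: 26 weeks per 6 months.
WEEKS_PER_MONTH = 26.0 / 6.0

MEASURES = ("par", "accelerometer")


@dataclass(frozen=True)
class OutcomeTimepoint:
    """Arm-level mean weekly MVPA minutes at one study week."""

    week: float
    mean_weekly_minutes: float
    sd: float = float("nan")
    n: int | None = None

    def __post_init__(self) -> None:
        if self.week < 0:
            raise InvalidParameterError(f"week must be >= 0, got {self.week}")
        if self.mean_weekly_minutes < 0:
            raise InvalidParameterError(
                f"mean_weekly_minutes must be >= 0, got {self.mean_weekly_minutes}"
            )


@dataclass(frozen=True)
class OutcomeSeries:
    """Ordered trajectory of weekly-minute means for one arm and measure."""

    arm: str
    measure: str
    timepoints: tuple[OutcomeTimepoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        if not self.timepoints:
            raise InvalidParameterError("OutcomeSeries needs at least one timepoint")
        weeks = [tp.week for tp in self.timepoints]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise InvalidParameterError(f"weeks must be strictly increasing, got {weeks}")
        if weeks[0] != 0:
            raise InvalidParameterError(
                f"series must start at week 0 (baseline), got first week {weeks[0]}"
            )

    @property
    def weeks(self) -> np.ndarray:
        return np.array([tp.week for tp in self.timepoints], dtype=float)

    @property
    def means(self) -> np.ndarray:
        return np.array([tp.mean_weekly_minutes for tp in self.timepoints], dtype=float)

    @property
    def baseline(self) -> float:
        return self.timepoints[0].mean_weekly_minutes


@dataclass(frozen=True)
class EffectivenessSummary:
    """Cumulative gain over a window, total and per month."""

    arm: str
    measure: str
    window: tuple[float, float]
    total_minutes_gained: float

    @property
    def window_months(self) -> float:
        return weeks_to_months(self.window[1] - self.window[0])

    @property
    def minutes_per_month(self) -> float:
        return gain_per_month(self.total_minutes_gained, self.window_months)


def interpolate_weekly_minutes(series: OutcomeSeries, week: float) -> float:
    """Piecewise-linear weekly-minutes value at an arbitrary study week.

    No extrapolation: requesting a week outside the measured range is an
    error rather than a guess.
    """
    weeks = series.weeks
    if not weeks[0] <= week <= weeks[-1]:
        raise InvalidParameterError(
            f"week {week} outside measured range [{weeks[0]}, {weeks[-1]}]; "
            "extrapolation is not supported"
        )
    return float(np.interp(week, weeks, series.means))


def cumulative_gain(series: OutcomeSeries, start_week: float, end_week: float) -> float:
    """Cumulative per-person minutes gained over [start_week, end_week].

    Trapezoidal integral of (interpolated weekly minutes - baseline
    weekly minutes) with respect to weeks.  Computed on the union of the
    window endpoints and the interior measurement weeks, which makes the
    integral exact for the piecewise-linear interpolant and makes
    adjacent windows add up exactly.
    """
    if start_week >= end_week:
        raise InvalidParameterError(
            f"need start_week < end_week, got {start_week} >= {end_week}"
        )
    baseline = series.baseline
    knots = [start_week]
    knots.extend(w for w in series.weeks if start_week < w < end_week)
    knots.append(end_week)
    total = 0.0
    for a, b in zip(knots, knots[1:]):
        fa = interpolate_weekly_minutes(series, a) - baseline
        fb = interpolate_weekly_minutes(series, b) - baseline
        total += (fa + fb) / 2.0 * (b - a)
    return total


def weeks_to_months(weeks: float) -> float:
    """Study weeks to months under the 26-weeks-per-6-months convention."""
    return weeks / WEEKS_PER_MONTH


def gain_per_month(total_minutes_gained: float, months: float) -> float:
    """Average per-person gain per month over a window."""
    if months <= 0:
        raise InvalidParameterError(f"months must be > 0, got {months}")
    return total_minutes_gained / months


def summarize(
    series: OutcomeSeries, start_week: float = 0.0, end_week: float | None = None
) -> EffectivenessSummary:
    """Convenience constructor for an EffectivenessSummary over a window."""
    if end_week is None:
        end_week = float(series.weeks[-1])
    return EffectivenessSummary(
        arm=series.arm,
        measure=series.measure,
        window=(start_week, end_week),
        total_minutes_gained=cumulative_gain(series, start_week, end_week),
    )
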