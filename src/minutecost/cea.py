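"""Cost-per-minute cost-effectiveness ratios.

Cost-effectiveness is expressed as US dollars per minute of MVPA
gained: the per-person cost of an arm over a horizon divided by the
per-person cumulative minute gain over the same horizon.  The
incremental ratio (ICER) divides the between-arm cost difference by the
between-arm gain difference.

Ratios are computed on unrounded per-person costs and unrounded gains;
rounding to cents happens only at reporting.  Rounding any earlier
changes the published cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .costs import HORIZONS, CostLedger
from .effectiveness import MEASURES, OutcomeSeries, cumulative_gain, gain_per_month
from .errors import ConfigurationError, InvalidParameterError, UndefinedRatioError
from .money import round_cents

__all__ = [
    "GainOverrides",
    "CEEntry",
    "CEResult",
    "cost_per_minute",
    "incremental_cost_per_minute",
    "horizon_gains",
    "build_ce_table",
]

#: Mapping (arm, measure, horizon_months) -> per-person total minute gain
#: that replaces the trapezoidal value (used when an analysis publishes
#: gain totals whose unrounded inputs are not recoverable).
GainOverrides = dict[tuple[str, str, int], float]


def cost_per_minute(per_person_cost: float, minutes_gained: float) -> float:
    """Dollars per minute of MVPA gained for one arm (unrounded)."""
    if minutes_gained == 0:
        raise UndefinedRatioError(
            "cost per minute is undefined when minutes_gained is zero"
        )
    return per_person_cost / minutes_gained


def incremental_cost_per_minute(
    cost_i: float, cost_c: float, gain_i: float, gain_c: float
) -> float:
    """Incremental dollars per incremental minute between two arms.

    The sign is preserved: a negative value means one arm both costs
    less and gains more (dominance) and is flagged downstream rather
    than silently clipped.
    """
    if gain_i == gain_c:
        raise UndefinedRatioError(
            "incremental ratio is undefined when both arms gain the same minutes"
        )
    return (cost_i - cost_c) / (gain_i - gain_c)


@dataclass(frozen=True)
class CEEntry:
    """One measure x horizon block of the cost-effectiveness table."""

    measure: str
    horizon_months: int
    gain_intervention: float
    gain_control: float
    per_person_cost_intervention: float
    per_person_cost_control: float

    @property
    def gain_per_month_intervention(self) -> float:
        return gain_per_month(self.gain_intervention, self.horizon_months)

    @property
    def gain_per_month_control(self) -> float:
        return gain_per_month(self.gain_control, self.horizon_months)

    @property
    def cost_per_minute_intervention(self) -> float:
        return round_cents(
            cost_per_minute(self.per_person_cost_intervention, self.gain_intervention)
        )

    @property
    def cost_per_minute_control(self) -> float:
        return round_cents(
            cost_per_minute(self.per_person_cost_control, self.gain_control)
        )

    @property
    def incremental_unrounded(self) -> float:
        return incremental_cost_per_minute(
            self.per_person_cost_intervention,
            self.per_person_cost_control,
            self.gain_intervention,
            self.gain_control,
        )

    @property
    def incremental_cost_per_minute(self) -> float:
        return round_cents(self.incremental_unrounded)

    @property
    def dominance(self) -> str | None:
        """'intervention' / 'control' when one arm dominates (negative ICER)."""
        if self.incremental_unrounded >= 0:
            return None
        cheaper_gains_more = (
            self.per_person_cost_intervention < self.per_person_cost_control
        )
        return "intervention" if cheaper_gains_more else "control"


@dataclass(frozen=True)
class CEResult:
    """Full cost-effectiveness table: every measure at every horizon."""

    entries: tuple[CEEntry, ...] = field(default_factory=tuple)

    def entry(self, measure: str, horizon_months: int) -> CEEntry:
        for e in self.entries:
            if e.measure == measure and e.horizon_months == horizon_months:
                return e
        raise KeyError((measure, horizon_months))

    def to_dict(self) -> dict:
        out: dict = {}
        for e in self.entries:
            key = f"{e.measure}_{e.horizon_months}mo"
            out[key] = {
                "total_minutes_intervention": round(e.gain_intervention, 1),
                "total_minutes_control": round(e.gain_control, 1),
                "minutes_per_month_intervention": round(e.gain_per_month_intervention),
                "minutes_per_month_control": round(e.gain_per_month_control),
                "cost_per_minute_intervention": e.cost_per_minute_intervention,
                "cost_per_minute_control": e.cost_per_minute_control,
                "incremental_cost_per_minute": e.incremental_cost_per_minute,
                "dominance": e.dominance,
            }
        return out

    def to_markdown(self) -> str:
        from .report import ce_table_markdown

        return ce_table_markdown(self)


def horizon_gains(
    series: OutcomeSeries,
    horizon_months: int,
    overrides: GainOverrides | None = None,
) -> float:
    """Per-person cumulative gain at a horizon, honouring overrides."""
    if overrides:
        key = (series.arm, series.measure, horizon_months)
        if key in overrides:
            return float(overrides[key])
    end_week = horizon_months * 26.0 / 6.0
    return cumulative_gain(series, 0.0, end_week)


def build_ce_table(
    ledger: CostLedger,
    series_map: dict[tuple[str, str], OutcomeSeries],
    overrides: GainOverrides | None = None,
    horizons: tuple[int, ...] = HORIZONS,
    measures: tuple[str, ...] = MEASURES,
) -> CEResult:
    """Assemble the full cost-effectiveness table.

    ``series_map`` must hold one OutcomeSeries per (arm, measure); a
    missing series is reported by name before any computation.
    """
    missing = [
        (arm, measure)
        for measure in measures
        for arm in ("intervention", "control")
        if (arm, measure) not in series_map
    ]
    if missing:
        raise ConfigurationError(f"missing outcome series for: {missing}")

    entries = []
    for measure in measures:
        for horizon in horizons:
            if horizon not in HORIZONS:
                raise InvalidParameterError(f"unsupported horizon {horizon} months")
            entries.append(
                CEEntry(
                    measure=measure,
                    horizon_months=horizon,
                    gain_intervention=horizon_gains(
                        series_map[("intervention", measure)], horizon, overrides
                    ),
                    gain_control=horizon_gains(
                        series_map[("control", measure)], horizon, overrides
                    ),
                    per_person_cost_intervention=ledger.per_person_cost(
                        "intervention", horizon
                    ),
                    per_person_cost_control=ledger.per_person_cost("control", horizon),
                )
            )
    return CEResult(entries=tuple(entries))
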