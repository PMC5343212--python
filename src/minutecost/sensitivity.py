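"""One-way deterministic sensitivity analysis and enrollment scaling.

Two scenario families:

* **Sensitivity grid** — recompute the incremental cost-per-minute
  ratios after multiplying a single input by a factor: either staffing
  costs (all staff-time ledger lines — training, delivery, and routine
  website maintenance — in both arms) or intervention effectiveness
  (the per-person minute gains in both arms).  Effectiveness scaling is
  exactly reciprocal on the ICER: scaling all gains by m divides the
  ratio by m.

* **Enrollment scaling** — decompose one arm's ledger into fixed costs
  (invariant to enrollment: hardware, hosting, technical support,
  training) and variable costs (per participant: materials and staff
  delivery/maintenance time, calibrated at the enrollment observed in
  the trial), and evaluate cost per person per month as a function of
  the number enrolled.  The curve decreases in n and approaches the
  variable cost per person per month asymptotically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import CEResult, GainOverrides, build_ce_table
from .costs import PERSONNEL_CATEGORIES, CostLedger
from .effectiveness import MEASURES, OutcomeSeries
from .errors import ConfigurationError, InvalidParameterError
from .money import round_cents

__all__ = [
    "SENSITIVITY_PARAMETERS",
    "SensitivitySpec",
    "ScalingCurve",
    "apply_sensitivity_to_ledger",
    "apply_sensitivity_to_gains",
    "sensitivity_table",
    "split_fixed_variable",
    "scaling_curve",
    "cost_per_person_per_month_at_n",
    "asymptotic_cost",
]

SENSITIVITY_PARAMETERS = ("staffing_costs", "intervention_effectiveness")


@dataclass(frozen=True)
class SensitivitySpec:
    """One scenario: which input to vary and by what factor."""

    parameter: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.parameter not in SENSITIVITY_PARAMETERS:
            raise InvalidParameterError(
                f"unknown sensitivity parameter {self.parameter!r}; "
                f"expected one of {SENSITIVITY_PARAMETERS}"
            )
        if self.multiplier <= 0:
            raise InvalidParameterError(
                f"multiplier must be > 0, got {self.multiplier}"
            )


def apply_sensitivity_to_ledger(ledger: CostLedger, spec: SensitivitySpec) -> CostLedger:
    """Scale the staff-time lines of both arms; leave everything else alone."""
    if spec.parameter != "staffing_costs":
        return ledger
    if spec.multiplier == 1.0:
        return ledger
    return ledger.with_items(
        it.scaled(spec.multiplier) if it.category in PERSONNEL_CATEGORIES else it
        for it in ledger.items
    )


def apply_sensitivity_to_gains(
    overrides: GainOverrides | None, spec: SensitivitySpec
) -> tuple[float, GainOverrides | None]:
    """Return the gain multiplier and pass-through overrides for a scenario.

    Gains are scaled analytically (one multiplier on both arms), which
    keeps the reciprocal ICER identity exact.
    """
    if spec.parameter != "intervention_effectiveness":
        return 1.0, overrides
    return spec.multiplier, overrides


@dataclass(frozen=True)
class SensitivityRow:
    """Incremental ratios for one scenario across measures and horizons."""

    label: str
    spec: SensitivitySpec | None
    incremental: dict[tuple[str, int], float]  # (measure, horizon) -> USD/minute


@dataclass(frozen=True)
class SensitivityTable:
    rows: tuple[SensitivityRow, ...]

    def cell(self, label: str, measure: str, horizon_months: int) -> float:
        for row in self.rows:
            if row.label == label:
                return row.incremental[(measure, horizon_months)]
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            row.label: {
                f"{measure}_{horizon}mo": value
                for (measure, horizon), value in sorted(row.incremental.items())
            }
            for row in self.rows
        }


def _scenario_ce(
    ledger: CostLedger,
    series_map: dict[tuple[str, str], OutcomeSeries],
    spec: SensitivitySpec | None,
    overrides: GainOverrides | None,
    horizons: tuple[int, ...],
    measures: tuple[str, ...],
) -> dict[tuple[str, int], float]:
    gain_mult = 1.0
    scenario_ledger = ledger
    if spec is not None:
        scenario_ledger = apply_sensitivity_to_ledger(ledger, spec)
        gain_mult, overrides = apply_sensitivity_to_gains(overrides, spec)
    table: CEResult = build_ce_table(
        scenario_ledger, series_map, overrides, horizons, measures
    )
    out = {}
    for entry in table.entries:
        # dividing the unrounded ICER by the gain multiplier is exact
        out[(entry.measure, entry.horizon_months)] = round_cents(
            entry.incremental_unrounded / gain_mult
        )
    return out


def sensitivity_table(
    ledger: CostLedger,
    series_map: dict[tuple[str, str], OutcomeSeries],
    deltas: tuple[float, ...] = (0.2,),
    overrides: GainOverrides | None = None,
    horizons: tuple[int, ...] = (6, 12),
    measures: tuple[str, ...] = MEASURES,
) -> SensitivityTable:
    """The one-way grid: standard row plus +/-delta rows per parameter."""
    if not deltas:
        raise ConfigurationError("sensitivity analysis needs at least one delta")
    rows = [
        SensitivityRow(
            label="standard",
            spec=None,
            incremental=_scenario_ce(
                ledger, series_map, None, overrides, horizons, measures
            ),
        )
    ]
    for parameter in SENSITIVITY_PARAMETERS:
        for delta in deltas:
            for sign, tag in ((+1, "+"), (-1, "-")):
                spec = SensitivitySpec(parameter, 1.0 + sign * delta)
                rows.append(
                    SensitivityRow(
                        label=f"{parameter}{tag}{delta:.0%}",
                        spec=spec,
                        incremental=_scenario_ce(
                            ledger, series_map, spec, overrides, horizons, measures
                        ),
                    )
                )
    return SensitivityTable(rows=tuple(rows))


@dataclass(frozen=True)
class ScalingCurve:
    """Fixed/variable cost decomposition as a function of enrollment."""

    fixed_total: float
    variable_per_person: float
    horizon_months: int
    arm: str = "intervention"

    def __post_init__(self) -> None:
        if self.fixed_total < 0 or self.variable_per_person < 0:
            raise InvalidParameterError("cost components must be >= 0")
        if self.horizon_months <= 0:
            raise InvalidParameterError("horizon_months must be > 0")

    def value(self, n: int | float) -> float:
        return cost_per_person_per_month_at_n(self, n)

    def asymptote(self) -> float:
        return asymptotic_cost(self)

    def grid(self, ns: np.ndarray) -> np.ndarray:
        ns = np.asarray(ns, dtype=float)
        return (self.fixed_total + ns * self.variable_per_person) / (
            ns * self.horizon_months
        )


def split_fixed_variable(
    ledger: CostLedger, arm: str, horizon_months: int
) -> tuple[float, float]:
    """(fixed total, variable cost per person) for one arm at a horizon.

    Variable cost per person is calibrated at the arm size observed in
    the trial.  The split uses each line's full amount at the horizon —
    the cumulative-total display exclusion does not apply, because a
    first-phase-only item is still bought once per participant.
    """
    fixed_cents = 0
    variable_cents = 0
    for it in ledger.arm_items(arm):
        cents = it.amount_cents_at(horizon_months)
        if it.scaling_role == "fixed":
            fixed_cents += cents
        else:
            variable_cents += cents
    n = ledger.n_for(arm)
    return fixed_cents / 100.0, variable_cents / 100.0 / n


def scaling_curve(
    ledger: CostLedger, arm: str = "intervention", horizon_months: int = 12
) -> ScalingCurve:
    fixed_total, variable_per_person = split_fixed_variable(ledger, arm, horizon_months)
    return ScalingCurve(
        fixed_total=fixed_total,
        variable_per_person=variable_per_person,
        horizon_months=horizon_months,
        arm=arm,
    )


def cost_per_person_per_month_at_n(curve: ScalingCurve, n: int | float) -> float:
    """Evaluate the enrollment curve at n participants."""
    if n <= 0:
        raise InvalidParameterError(f"number enrolled must be > 0, got {n}")
    return (curve.fixed_total + n * curve.variable_per_person) / (
        n * curve.horizon_months
    )


def asymptotic_cost(curve: ScalingCurve) -> float:
    """The n -> infinity limit: variable cost per person per month."""
    return curve.variable_per_person / curve.horizon_months
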