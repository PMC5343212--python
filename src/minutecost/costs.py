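"""Itemized payer-perspective cost model.

Builds the per-arm cost ledger of a two-arm intervention trial from
micro-costed components (staff hours at loaded wages, hardware
depreciation, materials, recurring website costs) and totals it at the
6- and 12-month horizons.

Loaded wages follow the ingredients approach: an annual salary
(optionally already including fringe benefits) is divided by the hours
in a work year and inflated by an overhead fraction for shared space.
Hardware is charged as straight-line depreciation over its useful life
for the years actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import InvalidParameterError
from .money import from_cents, round_cents, to_cents

__all__ = [
    "ARMS",
    "CATEGORIES",
    "PERSONNEL_CATEGORIES",
    "TIMINGS",
    "HORIZONS",
    "DEFAULT_HOURS_PER_YEAR",
    "PersonnelRate",
    "HardwareItem",
    "CostItem",
    "CostLedger",
    "ArmCostSummary",
    "hourly_rate",
    "loaded_hourly_rate",
    "personnel_cost",
    "straight_line_depreciation",
    "arm_total",
    "per_person_per_month",
]

ARMS = ("intervention", "control")

CATEGORIES = (
    "personnel_training",
    "personnel_delivery",
    "website_maintenance",
    "website_hosting",
    "website_technical_support",
    "hardware",
    "materials",
)

#: Categories that are staff time: these scale under a staffing-cost
#: sensitivity multiplier (training, delivery, and routine website
#: maintenance, which is performed by research staff).
PERSONNEL_CATEGORIES = frozenset(
    {"personnel_training", "personnel_delivery", "website_maintenance"}
)

TIMINGS = ("one_time", "recurring_monthly", "per_phase")

HORIZONS = (6, 12)

#: Hours in a full-time work year.  A 2000-hour year converts both
#: canonical loaded annual salaries ($86,520 and $56,153) to their
#: published hourly equivalents ($43.26 and $28.08) exactly.
DEFAULT_HOURS_PER_YEAR = 2000.0


def hourly_rate(
    annual_salary: float,
    fringe_frac: float = 0.0,
    hours_per_year: float = DEFAULT_HOURS_PER_YEAR,
) -> float:
    """Hourly wage from an annual salary, quoted to the cent.

    ``fringe_frac`` is the benefits fraction added on top of base
    salary; pass 0 when ``annual_salary`` is already fringe-loaded.
    Hourly wages are quoted in cents ($56,153 over a 2000-hour year is
    $28.08/h); the overhead loading is applied to the quoted wage.
    """
    if annual_salary < 0:
        raise InvalidParameterError(f"annual_salary must be >= 0, got {annual_salary}")
    if not 0 <= fringe_frac < 1:
        raise InvalidParameterError(f"fringe_frac must be in [0, 1), got {fringe_frac}")
    if hours_per_year <= 0:
        raise InvalidParameterError(f"hours_per_year must be > 0, got {hours_per_year}")
    return round_cents(annual_salary * (1.0 + fringe_frac) / hours_per_year)


def loaded_hourly_rate(base_hourly: float, overhead_frac: float) -> float:
    """Apply an overhead loading (e.g. 10% for shared space) to an hourly wage."""
    if base_hourly < 0:
        raise InvalidParameterError(f"base_hourly must be >= 0, got {base_hourly}")
    if overhead_frac < 0:
        raise InvalidParameterError(f"overhead_frac must be >= 0, got {overhead_frac}")
    return base_hourly * (1.0 + overhead_frac)


def personnel_cost(hours: float, loaded_rate: float) -> float:
    """Cost of staff time: hours x fully loaded hourly wage, rounded to cents."""
    if hours < 0:
        raise InvalidParameterError(f"hours must be >= 0, got {hours}")
    if loaded_rate < 0:
        raise InvalidParameterError(f"loaded_rate must be >= 0, got {loaded_rate}")
    return round_cents(hours * loaded_rate)


def straight_line_depreciation(
    purchase_price: float, life_years: float, use_years: float
) -> float:
    """Depreciated cost of equipment: price x use_years / life_years."""
    if purchase_price < 0:
        raise InvalidParameterError(f"purchase_price must be >= 0, got {purchase_price}")
    if life_years <= 0:
        raise InvalidParameterError(f"life_years must be > 0, got {life_years}")
    if not 0 < use_years <= life_years:
        raise InvalidParameterError(
            f"use_years must be in (0, life_years={life_years}], got {use_years}"
        )
    return round_cents(purchase_price * use_years / life_years)


@dataclass(frozen=True)
class PersonnelRate:
    """A staff wage rate.

    ``annual_salary`` may be a fringe-loaded annual figure (then
    ``fringe_frac`` stays 0) or a base salary with ``fringe_frac`` on
    top.  ``hourly_loaded`` includes the overhead fraction.
    """

    label: str
    annual_salary: float
    fringe_frac: float = 0.0
    overhead_frac: float = 0.0
    hours_per_year: float = DEFAULT_HOURS_PER_YEAR

    def __post_init__(self) -> None:
        # delegate range checks
        hourly_rate(self.annual_salary, self.fringe_frac, self.hours_per_year)
        if not 0 <= self.overhead_frac < 1:
            raise InvalidParameterError(
                f"overhead_frac must be in [0, 1), got {self.overhead_frac}"
            )

    @property
    def hourly_base(self) -> float:
        return hourly_rate(self.annual_salary, self.fringe_frac, self.hours_per_year)

    @property
    def hourly_loaded(self) -> float:
        return loaded_hourly_rate(self.hourly_base, self.overhead_frac)


@dataclass(frozen=True)
class HardwareItem:
    """Purchased equipment costed by straight-line depreciation."""

    label: str
    purchase_price: float
    life_years: float
    use_years: float

    def __post_init__(self) -> None:
        straight_line_depreciation(self.purchase_price, self.life_years, self.use_years)

    @property
    def depreciated_cost(self) -> float:
        return straight_line_depreciation(
            self.purchase_price, self.life_years, self.use_years
        )


@dataclass(frozen=True)
class CostItem:
    """One ledger line: a cost component of one arm at both horizons.

    Amounts are stored as integer cents.  ``amount_12mo_cents`` is
    cumulative (includes the first six months).  ``scaling_role``
    classifies the item as fixed (invariant to enrollment) or variable
    (scales per participant) for the enrollment-scaling model.

    ``in_cumulative_total`` handles ledgers whose published cumulative
    bottom line omits a first-phase-only item: when False the item is
    shown in itemized reports but excluded from 12-month totals.
    """

    label: str
    arm: str
    category: str
    timing: str
    amount_6mo_cents: int
    amount_12mo_cents: int
    scaling_role: str
    in_cumulative_total: bool = True

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidParameterError(f"{self.label!r}: unknown arm {self.arm!r}")
        if self.category not in CATEGORIES:
            raise InvalidParameterError(
                f"{self.label!r}: unknown category {self.category!r}"
            )
        if self.timing not in TIMINGS:
            raise InvalidParameterError(f"{self.label!r}: unknown timing {self.timing!r}")
        if self.scaling_role not in ("fixed", "variable"):
            raise InvalidParameterError(
                f"{self.label!r}: scaling_role must be fixed|variable, "
                f"got {self.scaling_role!r}"
            )
        if not 0 <= self.amount_6mo_cents <= self.amount_12mo_cents:
            raise InvalidParameterError(
                f"{self.label!r}: need 0 <= amount_6mo <= amount_12mo_cumulative, "
                f"got {self.amount_6mo_cents} and {self.amount_12mo_cents} cents"
            )
        if self.timing == "one_time" and self.amount_6mo_cents != self.amount_12mo_cents:
            raise InvalidParameterError(
                f"{self.label!r}: one_time items must have equal amounts at both horizons"
            )

    @property
    def amount_6mo(self) -> float:
        return from_cents(self.amount_6mo_cents)

    @property
    def amount_12mo_cumulative(self) -> float:
        return from_cents(self.amount_12mo_cents)

    def amount_cents_at(self, horizon_months: int, *, for_total: bool = False) -> int:
        """Cents contributed at a horizon; ``for_total`` applies the
        cumulative-total exclusion flag."""
        if horizon_months == 6:
            return self.amount_6mo_cents
        if horizon_months == 12:
            if for_total and not self.in_cumulative_total:
                return 0
            return self.amount_12mo_cents
        raise InvalidParameterError(
            f"horizon_months must be one of {HORIZONS}, got {horizon_months}"
        )

    def scaled(self, multiplier: float) -> "CostItem":
        """A copy with both amounts multiplied (used by sensitivity analysis)."""
        if multiplier <= 0:
            raise InvalidParameterError(f"multiplier must be > 0, got {multiplier}")
        return replace(
            self,
            amount_6mo_cents=to_cents(from_cents(self.amount_6mo_cents) * multiplier),
            amount_12mo_cents=to_cents(from_cents(self.amount_12mo_cents) * multiplier),
        )

    @classmethod
    def from_amounts(
        cls,
        label: str,
        arm: str,
        category: str,
        timing: str,
        amount_6mo: float,
        amount_12mo_cumulative: float,
        scaling_role: str,
        in_cumulative_total: bool = True,
    ) -> "CostItem":
        return cls(
            label=label,
            arm=arm,
            category=category,
            timing=timing,
            amount_6mo_cents=to_cents(amount_6mo),
            amount_12mo_cents=to_cents(amount_12mo_cumulative),
            scaling_role=scaling_role,
            in_cumulative_total=in_cumulative_total,
        )

    @classmethod
    def from_hours(
        cls,
        label: str,
        arm: str,
        category: str,
        rate: PersonnelRate,
        hours_6mo: float,
        hours_12mo_cumulative: float,
        scaling_role: str = "variable",
        timing: str = "per_phase",
        in_cumulative_total: bool = True,
    ) -> "CostItem":
        return cls.from_amounts(
            label,
            arm,
            category,
            timing,
            personnel_cost(hours_6mo, rate.hourly_loaded),
            personnel_cost(hours_12mo_cumulative, rate.hourly_loaded),
            scaling_role,
            in_cumulative_total,
        )

    @classmethod
    def from_hardware(
        cls,
        label: str,
        arm: str,
        hardware: HardwareItem,
        scaling_role: str = "fixed",
    ) -> "CostItem":
        amount = hardware.depreciated_cost
        return cls.from_amounts(
            label, arm, "hardware", "one_time", amount, amount, scaling_role
        )


@dataclass(frozen=True)
class ArmCostSummary:
    """Totals for one arm at one horizon, on per-person scales."""

    arm: str
    horizon_months: int
    total: float
    n_arm: int
    category_subtotals: dict[str, float] = field(default_factory=dict)

    @property
    def per_person(self) -> float:
        return self.total / self.n_arm

    @property
    def per_person_per_month(self) -> float:
        return self.per_person / self.horizon_months


@dataclass(frozen=True)
class CostLedger:
    """All cost items of a two-arm trial plus the arm sizes."""

    items: tuple[CostItem, ...]
    n_intervention: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_intervention <= 0 or self.n_control <= 0:
            raise InvalidParameterError(
                f"arm sizes must be positive, got n_intervention={self.n_intervention} "
                f"n_control={self.n_control}"
            )
        object.__setattr__(self, "items", tuple(self.items))

    def n_for(self, arm: str) -> int:
        if arm == "intervention":
            return self.n_intervention
        if arm == "control":
            return self.n_control
        raise InvalidParameterError(f"unknown arm {arm!r}")

    def arm_items(self, arm: str) -> tuple[CostItem, ...]:
        self.n_for(arm)  # validates the arm name
        return tuple(it for it in self.items if it.arm == arm)

    def arm_total_cents(self, arm: str, horizon_months: int) -> int:
        return sum(
            it.amount_cents_at(horizon_months, for_total=True)
            for it in self.arm_items(arm)
        )

    def arm_total(self, arm: str, horizon_months: int) -> float:
        return from_cents(self.arm_total_cents(arm, horizon_months))

    def per_person_cost(self, arm: str, horizon_months: int) -> float:
        """Unrounded per-person cost — the numerator of every CE ratio."""
        return self.arm_total(arm, horizon_months) / self.n_for(arm)

    def category_subtotals(self, arm: str, horizon_months: int) -> dict[str, float]:
        out: dict[str, int] = {}
        for it in self.arm_items(arm):
            cents = it.amount_cents_at(horizon_months, for_total=True)
            out[it.category] = out.get(it.category, 0) + cents
        return {cat: from_cents(c) for cat, c in out.items()}

    def summary(self, arm: str, horizon_months: int) -> ArmCostSummary:
        return ArmCostSummary(
            arm=arm,
            horizon_months=horizon_months,
            total=self.arm_total(arm, horizon_months),
            n_arm=self.n_for(arm),
            category_subtotals=self.category_subtotals(arm, horizon_months),
        )

    def with_items(self, items: Iterable[CostItem]) -> "CostLedger":
        return CostLedger(tuple(items), self.n_intervention, self.n_control)


def arm_total(ledger: CostLedger, arm: str, horizon_months: int) -> float:
    """Total cost of one arm at a horizon (sum of its ledger lines)."""
    return ledger.arm_total(arm, horizon_months)


def per_person_per_month(total: float, n: int, horizon_months: float) -> float:
    """Average cost per participant per month, rounded to cents."""
    if n <= 0:
        raise InvalidParameterError(f"cannot divide by arm size n={n}")
    if horizon_months <= 0:
        raise InvalidParameterError(f"horizon_months must be > 0, got {horizon_months}")
    return round_cents(total / n / horizon_months)
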