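"""File formats, analysis configuration, and the end-to-end pipeline.

CSV schemas
-----------
Cost ledger (``read_cost_ledger``): columns label, arm, category,
timing, basis, quantity_6mo, quantity_12mo, rate_ref, unit_price,
life_years, use_years, scaling_role, in_cumulative_total.  ``basis``
decides how the two horizon amounts are derived:

* ``amount`` — quantity columns are dollar amounts;
* ``hours`` — staff hours priced at the referenced loaded wage;
* ``unit`` — quantity x unit_price;
* ``purchase`` — straight-line depreciation of unit_price over
  life_years for use_years (one-time, same at both horizons).

Rates (``read_rates_csv``): label, loaded_annual_salary, overhead_frac,
hours_per_year.

Outcomes (``read_outcomes_csv``): arm, measure, week,
mean_weekly_minutes, sd, n.

Count streams (``read_count_streams``): participant_id, timestamp,
counts, worn.

Schema violations are reported with the offending row number.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .accelerometry import CountStream
from .cea import CEResult, GainOverrides, build_ce_table
from .costs import (
    CostItem,
    CostLedger,
    PersonnelRate,
    personnel_cost,
    straight_line_depreciation,
)
from .effectiveness import OutcomeSeries, OutcomeTimepoint
from .errors import ConfigurationError, SchemaError
from .money import round_cents, to_cents
from .report import (
    ce_table_markdown,
    cost_summary_markdown,
    scaling_markdown,
    sensitivity_markdown,
)
from .sensitivity import ScalingCurve, scaling_curve, sensitivity_table

__all__ = [
    "read_rates_csv",
    "read_cost_ledger",
    "write_cost_ledger",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "read_count_streams",
    "AnalysisConfig",
    "load_config",
    "run_pipeline",
]

_LEDGER_COLUMNS = [
    "label",
    "arm",
    "category",
    "timing",
    "basis",
    "quantity_6mo",
    "quantity_12mo",
    "rate_ref",
    "unit_price",
    "life_years",
    "use_years",
    "scaling_role",
    "in_cumulative_total",
]

_BASES = ("amount", "hours", "unit", "purchase")


def read_rates_csv(path) -> dict[str, PersonnelRate]:
    df = pd.read_csv(path)
    required = {"label", "loaded_annual_salary", "overhead_frac", "hours_per_year"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing rate columns {sorted(missing)}")
    rates = {}
    for i, row in df.iterrows():
        try:
            rates[str(row["label"])] = PersonnelRate(
                label=str(row["label"]),
                annual_salary=float(row["loaded_annual_salary"]),
                overhead_frac=float(row["overhead_frac"]),
                hours_per_year=float(row["hours_per_year"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return rates


def _item_amounts(row, rates: dict[str, PersonnelRate]) -> tuple[float, float]:
    basis = row["basis"]
    q6, q12 = float(row["quantity_6mo"]), float(row["quantity_12mo"])
    if q6 < 0 or q12 < 0:
        raise SchemaError(f"negative quantity ({q6}, {q12})")
    if basis == "amount":
        return q6, q12
    if basis == "hours":
        ref = str(row["rate_ref"])
        if ref not in rates:
            raise SchemaError(f"unknown rate_ref {ref!r}")
        loaded = rates[ref].hourly_loaded
        return personnel_cost(q6, loaded), personnel_cost(q12, loaded)
    if basis == "unit":
        price = float(row["unit_price"])
        return round_cents(q6 * price), round_cents(q12 * price)
    if basis == "purchase":
        dep = straight_line_depreciation(
            float(row["unit_price"]), float(row["life_years"]), float(row["use_years"])
        )
        return dep * q6, dep * q12
    raise SchemaError(f"unknown basis {basis!r}; expected one of {_BASES}")


def read_cost_ledger(
    path,
    n_intervention: int,
    n_control: int,
    rates: dict[str, PersonnelRate] | None = None,
) -> CostLedger:
    """Load and validate a cost-ledger CSV into a typed ledger."""
    df = pd.read_csv(path)
    missing = set(_LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing ledger columns {sorted(missing)}")
    items = []
    for i, row in df.iterrows():
        where = f"{path}: row {i + 2} ({row.get('label', '?')!r})"
        try:
            a6, a12 = _item_amounts(row, rates or {})
            items.append(
                CostItem.from_amounts(
                    label=str(row["label"]),
                    arm=str(row["arm"]),
                    category=str(row["category"]),
                    timing=str(row["timing"]),
                    amount_6mo=a6,
                    amount_12mo_cumulative=a12,
                    scaling_role=str(row["scaling_role"]),
                    in_cumulative_total=bool(int(row["in_cumulative_total"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return CostLedger(tuple(items), n_intervention, n_control)


def write_cost_ledger(ledger: CostLedger, path) -> None:
    """Write a ledger back out with basis=amount rows (lossless for the
    typed amount fields)."""
    rows = [
        {
            "label": it.label,
            "arm": it.arm,
            "category": it.category,
            "timing": it.timing,
            "basis": "amount",
            "quantity_6mo": it.amount_6mo,
            "quantity_12mo": it.amount_12mo_cumulative,
            "rate_ref": "",
            "unit_price": "",
            "life_years": "",
            "use_years": "",
            "scaling_role": it.scaling_role,
            "in_cumulative_total": int(it.in_cumulative_total),
        }
        for it in ledger.items
    ]
    pd.DataFrame(rows, columns=_LEDGER_COLUMNS).to_csv(path, index=False)


def read_outcomes_csv(path) -> dict[tuple[str, str], OutcomeSeries]:
    df = pd.read_csv(path)
    required = {"arm", "measure", "week", "mean_weekly_minutes", "sd", "n"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing outcome columns {sorted(missing)}")
    out = {}
    for (arm, measure), grp in df.groupby(["arm", "measure"]):
        grp = grp.sort_values("week")
        try:
            tps = tuple(
                OutcomeTimepoint(
                    week=float(r["week"]),
                    mean_weekly_minutes=float(r["mean_weekly_minutes"]),
                    sd=float(r["sd"]),
                    n=int(r["n"]),
                )
                for _, r in grp.iterrows()
            )
            out[(str(arm), str(measure))] = OutcomeSeries(
                arm=str(arm), measure=str(measure), timepoints=tps
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: series ({arm}, {measure}): {exc}") from exc
    return out


def write_outcomes_csv(series_map: dict[tuple[str, str], OutcomeSeries], path) -> None:
    rows = [
        {
            "arm": s.arm,
            "measure": s.measure,
            "week": tp.week,
            "mean_weekly_minutes": tp.mean_weekly_minutes,
            "sd": tp.sd,
            "n": tp.n,
        }
        for s in series_map.values()
        for tp in s.timepoints
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_streams(path) -> dict[str, CountStream]:
    df = pd.read_csv(path)
    required = {"participant_id", "timestamp", "counts", "worn"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing count-stream columns {sorted(missing)}")
    return {
        str(pid): CountStream(
            participant_id=str(pid),
            data=grp[["timestamp", "counts", "worn"]].reset_index(drop=True),
        )
        for pid, grp in df.groupby("participant_id")
    }


# ---------------------------------------------------------------------------
# analysis configuration and pipeline


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the end-to-end pipeline needs.

    Paths left as None fall back to the bundled reference dataset.
    ``gain_overrides`` maps (arm, measure, horizon_months) to published
    per-person gain totals that replace the trapezoidal values.
    """

    ledger_path: str | None = None
    rates_path: str | None = None
    outcomes_path: str | None = None
    n_intervention: int | None = None
    n_control: int | None = None
    horizons: tuple[int, ...] = (6, 12)
    sensitivity_deltas: tuple[float, ...] = (0.2,)
    scaling_grid: tuple[int, int, int] = (25, 1000, 25)  # start, stop, step
    use_default_gain_overrides: bool = True
    gain_overrides: GainOverrides = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for delta in self.sensitivity_deltas:
            if delta <= -1:
                raise ConfigurationError(f"sensitivity delta must be > -1, got {delta}")
        for name in ("ledger_path", "rates_path", "outcomes_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")

    def resolve(self) -> tuple[CostLedger, dict, GainOverrides]:
        from . import datasets

        rates = (
            read_rates_csv(self.rates_path)
            if self.rates_path
            else datasets.load_trial_rates()
        )
        n_i = self.n_intervention or datasets.TRIAL_N_INTERVENTION
        n_c = self.n_control or datasets.TRIAL_N_CONTROL
        ledger = (
            read_cost_ledger(self.ledger_path, n_i, n_c, rates)
            if self.ledger_path
            else datasets.load_trial_ledger()
        )
        series_map = (
            read_outcomes_csv(self.outcomes_path)
            if self.outcomes_path
            else datasets.load_trial_outcomes()
        )
        overrides: GainOverrides = {}
        if self.use_default_gain_overrides and not self.gain_overrides:
            overrides = dict(datasets.ACCELEROMETER_GAIN_TOTALS)
        overrides.update(self.gain_overrides)
        return ledger, series_map, overrides


def load_config(path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    overrides: GainOverrides = {}
    for entry in raw.pop("gain_overrides", []):
        overrides[(entry["arm"], entry["measure"], int(entry["horizon_months"]))] = float(
            entry["total_minutes"]
        )
    for key in ("horizons", "sensitivity_deltas", "scaling_grid"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    try:
        return AnalysisConfig(gain_overrides=overrides, **raw)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(
        {
            **{
                k: getattr(config, k)
                for k in (
                    "ledger_path",
                    "rates_path",
                    "outcomes_path",
                    "n_intervention",
                    "n_control",
                    "horizons",
                    "sensitivity_deltas",
                    "scaling_grid",
                    "use_default_gain_overrides",
                    "seed",
                )
            },
            "gain_overrides": sorted(
                (k[0], k[1], k[2], v) for k, v in config.gain_overrides.items()
            ),
        },
        sort_keys=True,
        default=list,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: AnalysisConfig, out_dir) -> dict[str, Path]:
    """Run the complete analysis and write the report bundle.

    Outputs (all deterministic for identical inputs and seed):
    cost_summary.{json,md}, ce_table.{json,md}, sensitivity.{json,md},
    scaling_curve.csv, run_log.json.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger, series_map, overrides = config.resolve()

    cost_summary = {
        f"{arm}_{h}mo": {
            "total": ledger.arm_total(arm, h),
            "per_person": round_cents(ledger.per_person_cost(arm, h)),
            "per_person_per_month": round_cents(ledger.per_person_cost(arm, h) / h),
            "by_category": ledger.category_subtotals(arm, h),
        }
        for arm in ("intervention", "control")
        for h in config.horizons
    }
    ce: CEResult = build_ce_table(
        ledger, series_map, overrides, horizons=config.horizons
    )
    sens = sensitivity_table(
        ledger,
        series_map,
        deltas=config.sensitivity_deltas,
        overrides=overrides,
        horizons=config.horizons,
    )
    curve: ScalingCurve = scaling_curve(ledger, "intervention", 12)
    start, stop, step = config.scaling_grid
    ns = list(range(start, stop + 1, step))
    curve_df = pd.DataFrame(
        {"n_enrolled": ns, "cost_per_person_per_month": [curve.value(n) for n in ns]}
    )

    paths: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        paths[name] = p

    _write("cost_summary.json", json.dumps(cost_summary, indent=2, sort_keys=True))
    _write("cost_summary.md", cost_summary_markdown(ledger) + "\n")
    _write("ce_table.json", json.dumps(ce.to_dict(), indent=2, sort_keys=True))
    _write("ce_table.md", ce_table_markdown(ce) + "\n")
    _write("sensitivity.json", json.dumps(sens.to_dict(), indent=2, sort_keys=True))
    _write("sensitivity.md", sensitivity_markdown(sens) + "\n")
    curve_path = out / "scaling_curve.csv"
    curve_df.to_csv(curve_path, index=False)
    paths["scaling_curve.csv"] = curve_path
    _write(
        "run_log.json",
        json.dumps(
            {
                "package": "minutecost",
                "version": __version__,
                "python": platform.python_version(),
                "seed": config.seed,
                "config_sha256": _config_hash(config),
                "scaling_asymptote": curve.asymptote(),
                "tolerances": {
                    "ledger_column_total_dollars": 2,
                    "note": "itemized inputs are rounded to whole dollars, so "
                    "column totals carry a +/-$2 reproduction tolerance",
                },
            },
            indent=2,
            sort_keys=True,
        ),
    )
    return paths
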