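"""Human-readable report rendering (Markdown tables).

Monetary precision follows the mixed convention of published costing
tables: whole dollars for totals, cents for per-minute ratios.
"""

from __future__ import annotations

from .cea import CEResult
from .costs import CostLedger
from .money import round_dollars
from .sensitivity import ScalingCurve, SensitivityTable

__all__ = [
    "markdown_table",
    "cost_summary_markdown",
    "ce_table_markdown",
    "sensitivity_markdown",
    "scaling_markdown",
]


def markdown_table(header: list[str], rows: list[list[str]]) -> str:
    """Minimal GitHub-flavoured Markdown table."""
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    lines.extend("| " + " | ".join(str(c) for c in row) + " |" for row in rows)
    return "\n".join(lines)


def cost_summary_markdown(ledger: CostLedger) -> str:
    rows = []
    for arm in ("intervention", "control"):
        for horizon in (6, 12):
            s = ledger.summary(arm, horizon)
            rows.append(
                [
                    arm,
                    f"{horizon} mo",
                    f"${round_dollars(s.total):,}",
                    f"${s.per_person:,.2f}",
                    f"${s.per_person_per_month:,.2f}",
                ]
            )
    return markdown_table(
        ["Arm", "Horizon", "Total", "Per person", "Per person per month"], rows
    )


def ce_table_markdown(result: CEResult) -> str:
    rows = []
    for e in result.entries:
        rows.append(
            [
                e.measure,
                f"{e.horizon_months} mo",
                f"{e.gain_intervention:.1f}",
                f"{e.gain_control:.1f}",
                f"${e.cost_per_minute_intervention:.2f}",
                f"${e.cost_per_minute_control:.2f}",
                f"${e.incremental_cost_per_minute:.2f}"
                + (f" (dominant: {e.dominance})" if e.dominance else ""),
            ]
        )
    return markdown_table(
        [
            "Measure",
            "Horizon",
            "Gain, intervention (min)",
            "Gain, control (min)",
            "$/min intervention",
            "$/min control",
            "Incremental $/min",
        ],
        rows,
    )


def sensitivity_markdown(table: SensitivityTable) -> str:
    keys = sorted(table.rows[0].incremental)
    header = ["Scenario"] + [f"{m} {h} mo" for m, h in keys]
    rows = [
        [row.label] + [f"${row.incremental[k]:.2f}" for k in keys] for row in table.rows
    ]
    return markdown_table(header, rows)


def scaling_markdown(curve: ScalingCurve, ns: list[int]) -> str:
    rows = [[str(n), f"${curve.value(n):.2f}"] for n in ns]
    rows.append(["asymptote", f"${curve.asymptote():.2f}"])
    return markdown_table(["Enrolled n", "Cost per person per month"], rows)
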