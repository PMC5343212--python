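"""Cost-effectiveness ratio tests: published table cells, error paths,
scale equivariance, and a cell-for-cell brute-force oracle."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from minutecost.cea import (
    build_ce_table,
    cost_per_minute,
    incremental_cost_per_minute,
)
from minutecost.costs import CostLedger
from minutecost.effectiveness import cumulative_gain
from minutecost.errors import ConfigurationError, UndefinedRatioError
from minutecost.money import round_cents


@pytest.mark.parametrize(
    "cost, gain, expected",
    [
        (10712 / 104, 1362.4, 0.08),
        (10712 / 104, 523, 0.20),
        (0, 1000, 0.0),
    ],
)
def test_cost_per_minute(cost, gain, expected):
    assert round_cents(cost_per_minute(cost, gain)) == expected


def test_cost_per_minute_zero_gain_is_explicit_error():
    with pytest.raises(UndefinedRatioError):
        cost_per_minute(100.0, 0.0)


@pytest.mark.parametrize(
    "ci, cc, gi, gc, expected",
    [
        (103.00, 48.51, 1362.4, 715, 0.08),
        (103.00, 48.51, 523, 186, 0.16),
        (50, 50, 100, 10, 0.0),
    ],
)
def test_incremental_cost_per_minute(ci, cc, gi, gc, expected):
    assert round_cents(incremental_cost_per_minute(ci, cc, gi, gc)) == expected


def test_incremental_equal_gains_is_explicit_error():
    with pytest.raises(UndefinedRatioError):
        incremental_cost_per_minute(100, 50, 20, 20)


@pytest.fixture(scope="module")
def table(trial_ledger, trial_outcomes, gain_overrides):
    return build_ce_table(trial_ledger, trial_outcomes, gain_overrides)


class TestTrialCETable:
    """Every published cost-effectiveness cell from ledger + series."""

    @pytest.mark.parametrize(
        "measure, horizon, interv, control",
        [
            ("par", 6, 0.08, 0.07),
            ("par", 12, 0.04, 0.03),
            ("accelerometer", 6, 0.20, 0.26),
            ("accelerometer", 12, 0.10, 0.11),
        ],
    )
    def test_per_arm_ratios(self, table, measure, horizon, interv, control):
        e = table.entry(measure, horizon)
        assert e.cost_per_minute_intervention == interv
        assert e.cost_per_minute_control == control

    @pytest.mark.parametrize(
        "measure, horizon, expected",
        [
            ("par", 6, 0.08),
            ("par", 12, 0.04),
            ("accelerometer", 6, 0.16),
            ("accelerometer", 12, 0.08),
        ],
    )
    def test_incremental_ratios(self, table, measure, horizon, expected):
        assert table.entry(measure, horizon).incremental_cost_per_minute == expected

    @pytest.mark.parametrize(
        "measure, horizon, interv, control",
        [
            ("par", 6, 1362, 715),
            ("par", 12, 4033, 2306),
            ("accelerometer", 6, 523, 186),
            ("accelerometer", 12, 1496, 696),
        ],
    )
    def test_total_gain_rows(self, table, measure, horizon, interv, control):
        e = table.entry(measure, horizon)
        assert round(e.gain_intervention) == interv
        assert round(e.gain_control) == control

    @pytest.mark.parametrize(
        "measure, horizon, interv, control",
        [
            ("par", 6, 227, 119),
            ("par", 12, 336, 192),
            ("accelerometer", 6, 87, 31),
            ("accelerometer", 12, 125, 58),
        ],
    )
    def test_per_month_gain_rows(self, table, measure, horizon, interv, control):
        e = table.entry(measure, horizon)
        assert round(e.gain_per_month_intervention) == interv
        assert round(e.gain_per_month_control) == control

    def test_no_dominance_flags(self, table):
        assert all(e.dominance is None for e in table.entries)

    def test_oracle_recomputation(self, table, trial_ledger, trial_outcomes, gain_overrides):
        """Brute-force recomputation of every cell from raw inputs."""
        for e in table.entries:
            costs, gains = {}, {}
            for arm in ("intervention", "control"):
                total = sum(
                    it.amount_cents_at(e.horizon_months, for_total=True)
                    for it in trial_ledger.items
                    if it.arm == arm
                ) / 100.0
                costs[arm] = total / trial_ledger.n_for(arm)
                key = (arm, e.measure, e.horizon_months)
                gains[arm] = gain_overrides.get(key) or cumulative_gain(
                    trial_outcomes[(arm, e.measure)], 0, e.horizon_months * 26 / 6
                )
            assert e.cost_per_minute_intervention == round_cents(
                costs["intervention"] / gains["intervention"]
            )
            assert e.cost_per_minute_control == round_cents(
                costs["control"] / gains["control"]
            )
            assert e.incremental_cost_per_minute == round_cents(
                (costs["intervention"] - costs["control"])
                / (gains["intervention"] - gains["control"])
            )


def test_missing_series_named(trial_ledger, trial_outcomes):
    partial = {k: v for k, v in trial_outcomes.items() if k[1] == "par"}
    with pytest.raises(ConfigurationError, match="accelerometer"):
        build_ce_table(trial_ledger, partial)


def test_all_zero_costs_give_zero_ratios(trial_ledger, trial_outcomes, gain_overrides):
    empty = CostLedger((), trial_ledger.n_intervention, trial_ledger.n_control)
    table = build_ce_table(empty, trial_outcomes, gain_overrides)
    for e in table.entries:
        assert e.cost_per_minute_intervention == 0.0
        assert e.cost_per_minute_control == 0.0
        assert e.incremental_cost_per_minute == 0.0


@given(k=st.floats(0.1, 10))
def test_scale_equivariance_in_costs(trial_ledger, trial_outcomes, gain_overrides, k):
    """Multiplying all costs by k multiplies every unrounded ratio by k."""
    base = build_ce_table(trial_ledger, trial_outcomes, gain_overrides)
    scaled_ledger = trial_ledger.with_items(it.scaled(k) for it in trial_ledger.items)
    scaled = build_ce_table(scaled_ledger, trial_outcomes, gain_overrides)
    for eb, es in zip(base.entries, scaled.entries):
        assert es.incremental_unrounded == pytest.approx(
            k * eb.incremental_unrounded, rel=1e-4
        )


@given(m=st.floats(0.2, 5))
def test_effectiveness_reciprocal_on_incremental(
    trial_ledger, trial_outcomes, gain_overrides, m
):
    """Scaling all gains by m divides the incremental ratio by m exactly."""
    base = build_ce_table(trial_ledger, trial_outcomes, gain_overrides)
    scaled_overrides = {
        (arm, measure, h): m
        * (
            gain_overrides.get((arm, measure, h))
            or cumulative_gain(trial_outcomes[(arm, measure)], 0, h * 26 / 6)
        )
        for arm in ("intervention", "control")
        for measure in ("par", "accelerometer")
        for h in (6, 12)
    }
    scaled = build_ce_table(trial_ledger, trial_outcomes, scaled_overrides)
    for eb, es in zip(base.entries, scaled.entries):
        assert es.incremental_unrounded * m == pytest.approx(
            eb.incremental_unrounded, rel=1e-9
        )
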