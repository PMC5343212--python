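"""Synthetic-trial generator tests: determinism, marginal calibration,
eligibility, dropout, and the staff-time log."""

import numpy as np
import pytest

from minutecost.costs import PersonnelRate
from minutecost.errors import ConfigurationError
from minutecost.simulate import (
    DEFAULT_RATES,
    StaffTask,
    TimepointSpec,
    TrialSimConfig,
    moment_match_censored_normal,
    records_to_frame,
    simulate_staff_log,
    simulate_trial,
    staff_log_to_cost_items,
    summarize_to_series,
)


class TestMomentMatching:
    @pytest.mark.parametrize(
        "mean, sd, upper",
        [
            (8.0, 15.0, 60.0),  # baseline under eligibility cap, CV > 1
            (8.5, 14.6, 60.0),
            (112.8, 97.1, None),
            (35.8, 69.7, None),  # CV ~ 1.9 without a cap
            (43.0, 60.9, None),
        ],
    )
    def test_matched_parent_reproduces_targets(self, mean, sd, upper):
        mu, sigma = moment_match_censored_normal(mean, sd, upper)
        rng = np.random.default_rng(0)
        x = rng.normal(mu, sigma, size=400_000)
        if upper is not None:
            x = x[x < upper]
        y = np.clip(x, 0, None)
        assert y.mean() == pytest.approx(mean, rel=0.02)
        assert y.std(ddof=1) == pytest.approx(sd, rel=0.02)

    def test_degenerate_sd_is_point_mass(self):
        assert moment_match_censored_normal(12.0, 0.0) == (12.0, 0.0)

    def test_mean_above_cap_rejected(self):
        with pytest.raises(ConfigurationError):
            moment_match_censored_normal(80.0, 10.0, 60.0)


class TestSimulateTrial:
    def test_deterministic_under_fixed_seed(self):
        cfg = TrialSimConfig(seed=11)
        a = records_to_frame(simulate_trial(cfg))
        b = records_to_frame(simulate_trial(cfg))
        assert a.equals(b)
        c = records_to_frame(simulate_trial(TrialSimConfig(seed=12)))
        assert not a.equals(c)

    def test_values_nonnegative_and_eligible(self):
        recs = simulate_trial(TrialSimConfig(seed=3).with_n(2000))
        for rec in recs:
            for (measure, week), v in rec.values.items():
                if v is not None:
                    assert v >= 0
                if measure == "par" and week == 0:
                    assert v < 60.0

    def test_dropouts_lack_followup_values(self):
        recs = simulate_trial(TrialSimConfig(seed=3))
        for rec in recs:
            if not rec.completed:
                assert rec.values[("par", 26.0)] is None
                assert rec.values[("par", 0.0)] is not None

    def test_completer_fraction_binomial(self):
        cfg = TrialSimConfig(seed=5, dropout=0.161).with_n(10_000)
        recs = simulate_trial(cfg)
        frac = sum(r.completed for r in recs) / len(recs)
        se = np.sqrt(0.161 * 0.839 / 20_000)
        assert abs(frac - 0.839) < 3 * se

    def test_dropout_independent_of_baseline(self):
        recs = simulate_trial(TrialSimConfig(seed=9).with_n(5000))
        base_c = [r.values[("par", 0.0)] for r in recs if r.completed]
        base_d = [r.values[("par", 0.0)] for r in recs if not r.completed]
        pooled_se = np.sqrt(np.var(base_c) / len(base_c) + np.var(base_d) / len(base_d))
        assert abs(np.mean(base_c) - np.mean(base_d)) < 3 * pooled_se


class TestSummarize:
    def test_zero_variance_config_recovers_means_exactly(self):
        params = {
            ("intervention", "par"): (
                TimepointSpec(0, 8.0, 0.0),
                TimepointSpec(26, 50.0, 0.0),
            ),
            ("control", "par"): (
                TimepointSpec(0, 8.5, 0.0),
                TimepointSpec(26, 30.0, 0.0),
            ),
        }
        cfg = TrialSimConfig(seed=1, outcome_params=params)
        series = summarize_to_series(simulate_trial(cfg))
        s = series[("intervention", "par")]
        assert s.means.tolist() == [8.0, 50.0]
        assert all(tp.sd == 0.0 for tp in s.timepoints)

    def test_followup_n_equals_completer_count(self):
        recs = simulate_trial(TrialSimConfig(seed=2))
        series = summarize_to_series(recs)
        completers = sum(1 for r in recs if r.completed and r.arm == "intervention")
        assert series[("intervention", "par")].timepoints[1].n == completers

    def test_needs_two_completers_per_arm(self):
        recs = simulate_trial(TrialSimConfig(seed=2).with_n(5))
        for r in recs:
            if r.arm == "control":
                r.completed = False
        with pytest.raises(ConfigurationError):
            summarize_to_series(recs)


class TestStaffLog:
    def test_empty_catalog_empty_log(self):
        cfg = TrialSimConfig(seed=0, staff_catalog=())
        log = simulate_staff_log(cfg)
        assert log.empty
        assert staff_log_to_cost_items(log) == []

    def test_deterministic_under_fixed_seed(self):
        cfg = TrialSimConfig(seed=21)
        assert simulate_staff_log(cfg).equals(simulate_staff_log(cfg))

    def test_unknown_rate_label_rejected(self):
        bad = (
            StaffTask("call", "intervention", "personnel_delivery", 1, 10.0, "ceo"),
        )
        with pytest.raises(ConfigurationError):
            simulate_staff_log(TrialSimConfig(seed=0, staff_catalog=bad))

    def test_calibrated_catalog_reproduces_delivery_cost(self):
        """Delivery minutes chosen to hit the observed $5674 phase-1
        intervention delivery cost at the loaded RA rate."""
        ra = DEFAULT_RATES["research_associate"]
        minutes = 5674.0 / ra.hourly_loaded / 104 * 60
        catalog = (
            StaffTask(
                "delivery", "intervention", "personnel_delivery", 1, minutes,
                "research_associate",
            ),
        )
        cfg = TrialSimConfig(seed=0, staff_catalog=catalog)
        items = staff_log_to_cost_items(simulate_staff_log(cfg))
        (item,) = items
        assert item.amount_6mo == pytest.approx(5674, abs=10)

    def test_default_catalog_matches_trial_personnel_structure(self, trial_ledger):
        """Expected staff-log costs land near the observed personnel
        ledger lines (stochastic failed attempts allow ~2% drift)."""
        cfg = TrialSimConfig(seed=4)
        items = {
            (it.arm, it.category): it
            for it in staff_log_to_cost_items(simulate_staff_log(cfg))
        }
        observed = {
            ("intervention", "personnel_training"): (471, 471),
            ("intervention", "personnel_delivery"): (5674, 8083),
            ("intervention", "website_maintenance"): (270, 490),
            ("control", "personnel_training"): (157, 157),
            ("control", "personnel_delivery"): (1976, 3119),
            ("control", "website_maintenance"): (8, 10),
        }
        for key, (a6, a12) in observed.items():
            item = items[key]
            assert item.amount_6mo == pytest.approx(a6, rel=0.05, abs=2)
            assert item.amount_12mo_cumulative == pytest.approx(a12, rel=0.05, abs=2)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        TrialSimConfig(dropout=1.0)
    with pytest.raises(ConfigurationError):
        TrialSimConfig(n_intervention=0)
    with pytest.raises(ConfigurationError):
        TimepointSpec(0, 8.0, -1.0)
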