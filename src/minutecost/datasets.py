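"""Bundled reference dataset.

The packaged CSVs carry the published inputs of a 12-month randomized
trial of a Spanish-language, web-delivered physical-activity program
for underactive Latina women (104 intervention / 101 control): the
itemized payer-perspective cost ledger at the 6- and 12-month
horizons, the staff wage rates behind its personnel lines, and the
arm-level weekly-MVPA outcome series for both measures (7-Day PAR
interview and hip-worn accelerometer).
"""

from __future__ import annotations

from importlib import resources

from .cea import GainOverrides
from .costs import CostLedger, PersonnelRate
from .effectiveness import OutcomeSeries

__all__ = [
    "TRIAL_N_INTERVENTION",
    "TRIAL_N_CONTROL",
    "ACCELEROMETER_GAIN_TOTALS",
    "data_path",
    "load_trial_rates",
    "load_trial_ledger",
    "load_trial_outcomes",
]

TRIAL_N_INTERVENTION = 104
TRIAL_N_CONTROL = 101

#: Published per-person accelerometer gain totals (minutes).  The
#: trapezoid of the published (rounded) weekly means differs slightly
#: (520.0 / 185.9 at 6 months; 1489.8 / 720.2 at 12 months) because the
#: unrounded inputs behind the published totals are not recoverable;
#: downstream ratios use these totals as overrides.
ACCELEROMETER_GAIN_TOTALS: GainOverrides = {
    ("intervention", "accelerometer", 6): 523.0,
    ("control", "accelerometer", 6): 186.3,
    ("intervention", "accelerometer", 12): 1496.0,
    ("control", "accelerometer", 12): 696.0,
}


def data_path(name: str):
    """Filesystem path of a bundled data file."""
    return resources.files("minutecost.data") / name


def load_trial_rates() -> dict[str, PersonnelRate]:
    from .io import read_rates_csv

    return read_rates_csv(data_path("staff_rates.csv"))


def load_trial_ledger() -> CostLedger:
    from .io import read_cost_ledger

    return read_cost_ledger(
        data_path("trial_costs.csv"),
        n_intervention=TRIAL_N_INTERVENTION,
        n_control=TRIAL_N_CONTROL,
        rates=load_trial_rates(),
    )


def load_trial_outcomes() -> dict[tuple[str, str], OutcomeSeries]:
    from .io import read_outcomes_csv

    return read_outcomes_csv(data_path("trial_outcomes.csv"))
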