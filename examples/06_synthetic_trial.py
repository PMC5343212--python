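"""End-to-end run on a synthetic trial.

Generates per-participant trajectories calibrated to the bundled
trial's completer means/SDs (zero-censored normal marginals, Gaussian
copula across timepoints, 16.1% dropout), summarizes completers into
arm-level series, and recomputes the cost-effectiveness table.
"""

from minutecost import build_ce_table, datasets
from minutecost.simulate import TrialSimConfig, simulate_trial, summarize_to_series

config = TrialSimConfig(seed=7)
records = simulate_trial(config)
completers = sum(r.completed for r in records)
print(f"simulated {len(records)} participants, {completers} completers")

series = summarize_to_series(records)
for key in sorted(series):
    tps = series[key].timepoints
    print(key, [(tp.week, round(tp.mean_weekly_minutes, 1)) for tp in tps])

table = build_ce_table(datasets.load_trial_ledger(), series)
e = table.entry("par", 6)
print(f"6-month self-report ICER on synthetic data: ${e.incremental_cost_per_minute}/min")

# At the real trial's size (104/101) the synthetic ICER scatters around
# the $0.08/min implied by the configured means; at n=5000/arm the
# recomputed statistics land within Monte-Carlo error of the configured
# values (see the test suite's parameter-recovery check).
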