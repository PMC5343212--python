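"""Cumulative MVPA gains and the cost-per-minute table.

Interpolates the arm-level weekly-MVPA means (weeks 0/26/52) and
divides per-person costs by per-person minute gains.
"""

from minutecost import build_ce_table, cumulative_gain, datasets

ledger = datasets.load_trial_ledger()
outcomes = datasets.load_trial_outcomes()

interv = outcomes[("intervention", "par")]
print("Intervention self-report gain, weeks 0-26:", round(cumulative_gain(interv, 0, 26), 1))
print("Intervention self-report gain, weeks 0-52:", round(cumulative_gain(interv, 0, 52), 1))

table = build_ce_table(ledger, outcomes, datasets.ACCELEROMETER_GAIN_TOTALS)
print()
print(table.to_markdown())

# A participant in the intervention arm gains 1362.4 self-reported MVPA
# minutes over the first 26 weeks (the area between her interpolated
# weekly-minutes curve and its baseline).  At $103 per person that is
# $0.08 per minute gained; the incremental ratio versus the control arm
# is also $0.08/min at 6 months and halves to $0.04/min by 12 months.
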