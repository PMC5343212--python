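# minutecost

Payer-perspective costing and **cost-per-minute cost-effectiveness
analysis** of physical-activity interventions, built for two-arm trials
whose outcome is weekly minutes of moderate- to vigorous-intensity
physical activity (MVPA).

Health-economic evaluations of behavioral programs rarely reach
quality-adjusted life years; the practical currency is *dollars per
minute of activity gained*. `minutecost` implements that chain end to
end for trial analysts and implementation researchers:

* **Micro-costing** — an itemized per-arm cost ledger: staff hours at
  loaded wages (salary × (1+fringe)/hours × (1+overhead)), straight-line
  hardware depreciation, materials, and recurring website costs, totaled
  at 6- and 12-month horizons.
* **Effectiveness** — cumulative per-person MVPA gain by trapezoidal
  integration of piecewise-linearly interpolated weekly means:
  for one segment, (Δmean/2) × weeks, with 26 weeks ≡ 6 months.
* **Cost-effectiveness** — per-arm ratios C/E and the incremental ratio
  ICER = (C_i − C_c)/(E_i − E_c), computed unrounded and reported in
  cents.
* **Scenario analysis** — one-way ±20% sensitivity on staffing costs and
  on effectiveness (exactly reciprocal on the ICER), and an
  enrollment-scaling model (fixed + n·variable)/(n·months) with its
  asymptote.
* **Accelerometry** — MVPA bout scoring of minute-level count streams
  (≥1952 counts/min in bouts of ≥10 consecutive worn minutes) and
  wear-time validity (10 h × 5 days, or 3000 min over 4 days).
* **Synthetic trials** — a calibrated generator (zero-censored-normal
  marginals, Gaussian copula, eligibility screening, dropout, staff-time
  logs) so every pipeline stage runs without external data.

The package bundles the published inputs of a 12-month randomized trial
of a Spanish-language web-delivered physical-activity program for
underactive Latina women (104 intervention / 101 control) and reproduces
its full published analysis; see `minutecost.datasets`.

## Worked example

```python
from minutecost import build_ce_table, datasets, scaling_curve, sensitivity_table

ledger   = datasets.load_trial_ledger()     # itemized costs, both arms
outcomes = datasets.load_trial_outcomes()   # weekly MVPA means, weeks 0/26/52

ledger.arm_total("intervention", 6)         # 10712.0  (USD, first 6 months)
ledger.summary("intervention", 6).per_person_per_month   # 17.17

table = build_ce_table(ledger, outcomes, datasets.ACCELEROMETER_GAIN_TOTALS)
print(table.to_markdown())
```

```
| Measure | Horizon | Gain, intervention (min) | Gain, control (min) | $/min intervention | $/min control | Incremental $/min |
| --- | --- | --- | --- | --- | --- | --- |
| par | 6 mo | 1362.4 | 715.0 | $0.08 | $0.07 | $0.08 |
| par | 12 mo | 4032.6 | 2306.2 | $0.04 | $0.03 | $0.04 |
| accelerometer | 6 mo | 523.0 | 186.3 | $0.20 | $0.26 | $0.16 |
| accelerometer | 12 mo | 1496.0 | 696.0 | $0.10 | $0.11 | $0.08 |
```

Reading the first row: over the first 26 weeks an intervention
participant gains 1362.4 self-reported MVPA minutes (the area between
her interpolated weekly-minutes curve and baseline) at $103 per person,
i.e. $0.08 per minute; the extra gain over the control arm also costs
$0.08 per extra minute. By 12 months the incremental cost halves to
$0.04/min.

Enrollment scaling:

```python
curve = scaling_curve(ledger, "intervention", 12)
[round(curve.value(n)) for n in (50, 100, 200)]   # [16, 12, 10]
round(curve.asymptote(), 2)                       # 8.51  ("near $8")
```

Each `examples/*.py` script demonstrates one capability with commentary;
a thin CLI mirrors them (`minutecost run|costs|ce|sensitivity|scale|
simulate|score-accel`).

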