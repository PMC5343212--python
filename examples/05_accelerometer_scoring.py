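"""Scoring minute-level accelerometer counts into MVPA minutes.

A minute counts toward MVPA only inside a bout: >= 10 consecutive worn
minutes at >= 1952 counts/min.  Wear validity requires 10 h of wear on
5 days, or 3000 total minutes over 4 days.
"""

import numpy as np

from minutecost import CountStream, mvpa_minutes, wear_valid
from minutecost.simulate import simulate_count_minutes

rng = np.random.default_rng(42)
stream = CountStream("demo", simulate_count_minutes(rng, days=7, bouts_per_day=1.5))

minutes = mvpa_minutes(stream)
per_day = stream.wear_minutes_per_day()
print(f"weekly MVPA minutes in bouts: {minutes}")
print(f"wear minutes per day: {per_day.tolist()}")
print(f"valid wear week: {wear_valid(per_day)}")

# Only sustained activity counts: isolated above-threshold minutes and
# runs shorter than 10 minutes contribute nothing, which is why
# accelerometer-measured MVPA is far below self-reported MVPA.
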