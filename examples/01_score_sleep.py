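"""Score sleep on a hand-built activity trace.

Fly sleep is >=5 consecutive minutes without a beam crossing.  The trace
below has zero-runs of 5, 4 and 5 minutes: the 4-min run stays awake, so
the fly sleeps 10 of 17 minutes, in two 5-min bouts.
"""

import numpy as np

from flysleep import ActivityTable, score_sleep, sleep_bouts, sleep_in_window

counts = np.array([[0, 0, 0, 0, 0, 3, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 2]])
table = ActivityTable(counts=counts, fly_ids=["fly-A"])

series = score_sleep(table)
print(f"total sleep: {series.total_sleep()[0]} min of {table.n_minutes}")
for b in sleep_bouts(series):
    print(f"  bout at t={b.start_t}, {b.duration} min")
print(f"sleep in window [14, 17): {sleep_in_window(series, 14, 17)[0]} min "
      "(the straddling bout contributes only its in-window minutes)")
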