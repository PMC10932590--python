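"""Derive eye-tracking reading measures from a scan path, apply filters.

Traces a short fixation record with a regression and shows how the three
duration measures treat it; then applies a self-paced-reading exclusion
protocol to a toy response table.
"""

import pandas as pd

from ctdreg.measures import (
    FilterConfig,
    Fixation,
    apply_filters,
    first_pass_durations,
    go_past_durations,
    scan_path_durations,
)

# regions fixated in order 1 -> 2 -> back to 1 -> 3 (a regression from 2)
path, t = [], 0.0
for region, dur in [(1, 0.200), (2, 0.150), (1, 0.100), (3, 0.080)]:
    path.append(Fixation(region, t, t + dur))
    t += dur

print("scan path durations (every visit):", scan_path_durations(path))
print("first-pass durations (first leftward visits):", first_pass_durations(path))
gp, unresolved = go_past_durations(path, return_unresolved=True)
print("go-past durations (regression time included):", gp)
print("go-past unresolved at record end:", unresolved)
print("note go-past(2) = 150 + 100 = 250 ms: the regression to 1 counts")

responses = pd.DataFrame(
    {
        "participant_id": [0, 0, 0, 1, 1, 1],
        "duration_ms": [50.0, 500.0, 3500.0, 450.0, 520.0, 610.0],
    }
)
kept, log = apply_filters(responses, FilterConfig(rt_min=100, rt_max=3000))
print(f"\nRT bounds [100, 3000] ms keep {log['n_kept']}/{log['n_in']} responses;"
      f" exclusions by rule: {log['counts']}")
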