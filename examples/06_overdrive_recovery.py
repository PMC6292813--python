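"""Corrected recovery time (cRT) after overdrive pacing.

Emulates the standard protocol — pacing trains at 75% of the spontaneous
cycle length, then a suppressed first spontaneous beat — and computes
cRT = (first spontaneous beat - last paced beat) - spontaneous cycle length,
averaged over three trains.
"""

import numpy as np

from biopace import corrected_recovery_time

spontaneous_cl = 416.0  # ms, a bradycardic subsidiary-pacemaker rhythm
rng = np.random.default_rng(7)

train_ends, beats = [], []
t = 0.0
for train in range(3):
    t += 120_000.0                     # 2 min pacing train
    train_ends.append(t)
    # overdrive suppression delays the first recovery beat beyond one CL
    suppression = 125.0 + rng.normal(0.0, 10.0)
    first = t + spontaneous_cl + suppression
    beats.extend(first + np.arange(0, 10) * spontaneous_cl)
    t = beats[-1]

res = corrected_recovery_time(beats, train_ends, spontaneous_cl)
print(f"spontaneous CL : {res.spontaneous_cl:.0f} ms")
print(f"per-train cRT  : {np.round(res.crts, 1)} ms")
print(f"mean cRT       : {res.crt:.1f} ms "
      f"(recovery time minus one spontaneous cycle; larger = more "
      f"overdrive suppression)")
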