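"""Conditioned inhibitors: immune to exposure, vulnerable to time.

Two classic inhibition results: presenting a safety signal on its own
does not extinguish it (a consequence of rectified prediction), and
inhibition - unlike excitation - fades over a retention interval.
"""

import numpy as np

from fearsim import build, run_and_evaluate, simulate


def w_at(tr, feature, stage):
    i = tr.feature_index(feature)
    return tr.w[int(np.flatnonzero(tr.seq.stage == stage)[-1]), i]


trajs, results = run_and_evaluate(build("inhibitor_nonextinction"))
tr = trajs["main"]
print("inhibitor exposed alone (rectified prediction):")
print(f"  w_X before exposure: {w_at(tr, 'X', 'training'):+.4f}")
print(f"  w_X after  exposure: {w_at(tr, 'X', 'exposure'):+.4f}   (identical)")
for r in results:
    print("  " + r.describe())

linear = simulate(build("inhibitor_nonextinction", rectify=False))["main"]
print("same schedule with linear (unrectified) prediction:")
print(f"  w_X before exposure: {w_at(linear, 'X', 'training'):+.4f}")
print(f"  w_X after  exposure: {w_at(linear, 'X', 'exposure'):+.4f}   (wrongly unlearned)")

print("\nforgetting of inhibition (decay model, 1000-step delay):")
_, results = run_and_evaluate(build("forgetting_of_inhibition"))
for r in results:
    print("  " + r.describe())
print(
    "The response to A alone is preserved across the delay while the A.X\n"
    "compound loses X's protection: only the negative weight decayed."
)
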