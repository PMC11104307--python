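"""Gradual extinction under competitive attention (Revised CompAct).

Occasional reinforced trials early in extinction keep the CS a usable
predictor, holding attention on the CS instead of letting it shift to
the context; the CS-US association is driven down further and less fear
returns after a 1000-step retention interval.
"""

import numpy as np

from fearsim import build, run_and_evaluate
from fearsim.metrics import test_response

trajs, results = run_and_evaluate(build("gradual_extinction"))
print("post-delay test response:")
for g in ("Gradual", "GradualReverse", "Standard"):
    print(f"  {g:<15} {test_response(trajs[g], 'test'):.4f}")
for r in results:
    print(r.describe())

print("\nmean attention to the CS on extinction trials:")
for g in ("Gradual", "GradualReverse", "Standard"):
    tr = trajs[g]
    a_cs = np.nanmean(tr.a[tr.trial_mask(stage="extinction"), tr.feature_index("CS")])
    print(f"  {g:<15} a_CS = {a_cs:.3f}")
print(
    "Reinforcers placed early (but not late) keep attention on the CS, which\n"
    "is why only the Gradual schedule deepens extinction."
)
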