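"""Spontaneous recovery as decay of inhibition, and its predicted
context dependence.

Under the decay-of-inhibition model (rho = 0.002, lam = 0.3) only
negative weights shrink during a retention interval, so the extinction
context's safety signal fades while the CS-US association stays put.
"""

from fearsim import build, run_and_evaluate
from fearsim.metrics import test_response

p = build("spontaneous_recovery", delays=(0, 250, 1000))
trajs, results = run_and_evaluate(p)
print("test response by retention interval (decay model):")
for d in (0, 250, 1000):
    print(f"  {d:>4} steps: {test_response(trajs[f'delay{d}'], 'test'):.4f}")

tr = trajs["delay1000"]
print(f"  CS weight across the 1000-step delay: unchanged at {tr.weight('CS'):+.3f}")

basic_trajs, _ = run_and_evaluate(p.with_variant("basic"))
flat = [test_response(basic_trajs[f"delay{d}"], "test") for d in (0, 250, 1000)]
print(f"basic model (no decay): {[round(v, 4) for v in flat]}  - no recovery")

print("\npredicted context dependence of recovery:")
_, results = run_and_evaluate(build("sr_context_dependence"))
for r in results:
    print(r.describe())
print(
    "The delay only helps in the extinction context, because what decays is\n"
    "that context's inhibition - a testable prediction."
)
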