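"""What extinction actually does to the underlying associations.

Runs 10 conditioning trials (CS+) then 30 extinction trials (CS-) in a
single context with the basic delta-rule learner (lam = 0.3), once with a
context feature and once context-blind, and prints the final weights.
"""

from fearsim import (
    Design,
    ModelParams,
    Stage,
    StimulusCatalog,
    TrialSpec,
    build_basis,
    run,
)

catalog = StimulusCatalog(cs_labels=("CS",), context_labels=("A",))
design = Design(
    catalog=catalog,
    trial_specs={
        "CS+": TrialSpec("CS+", {"CS"}, us=1),
        "CS-": TrialSpec("CS-", {"CS"}, us=0),
    },
    groups={
        "main": (
            Stage("conditioning", "A", ("CS+",) * 10),
            Stage("extinction", "A", ("CS-",) * 30),
        )
    },
)
params = ModelParams.defaults("basic")

tr = run(design, "main", params)
print("with a context feature:")
print(f"  final extinction-trial prediction  y_hat = {tr.trial_y_hat(stage='extinction')[-1]:.4f}")
print(f"  CS weight  w_CS  = {tr.weight('CS'):+.4f}   (threat association survives)")
print(f"  context    w_A   = {tr.weight('A'):+.4f}   (context became a safety signal)")

blind = build_basis(catalog, include_contexts=False)
tr2 = run(design, "main", params, basis=blind)
print("context-blind learner:")
print(f"  CS weight  w_CS  = {tr2.weight('CS'):+.6f}  (pure unlearning: association erased)")

print(
    "\nThe response goes to zero either way, but only the context-aware learner\n"
    "keeps a hidden CS-US association masked by context inhibition - the raw\n"
    "material for renewal, spontaneous recovery and reinstatement."
)
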