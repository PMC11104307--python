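# fearsim

Simulation of Pavlovian fear extinction and the **return of fear** with
Rescorla–Wagner-family learning models.

Exposure therapy works by extinction — presenting a feared stimulus
without harmful consequences — yet fear routinely returns: in a new
situation (*renewal*), with the passage of time (*spontaneous
recovery*), or after a fresh encounter with the aversive event
(*reinstatement*). `fearsim` is a small, fully deterministic simulator
for the family of trial-level associative models that explain all three
effects through one principle: extinction does not erase the threat
association, it buries it under **conditioned inhibition by the
extinction context** (a learned safety signal). The package is aimed at
computational-psychiatry and learning-theory researchers who want to
run, modify or extend these simulations.

## The models

Time is divided into discrete steps; on each step the learner sees a
cue vector *xₙ* (discrete CSs plus one context), maps it to features
*f(xₙ)* (elemental, optionally pairwise configural), predicts the US as
a positively rectified weighted sum

    ŷ(xₙ) = max( Σᵢ fᵢ(xₙ) wᵢ , 0 )

and updates weights from the prediction error *yₙ − ŷ(xₙ)*. Five
variants share this skeleton:

| variant | update rule | adds |
|---|---|---|
| `basic` | *wᵢ ← wᵢ + λ fᵢ (y − ŷ)* | rectified prediction |
| `configural` | same rule | CS×CS and CS×context configural features |
| `decay` | … *− I[wᵢ<0] ρ wᵢ* on every step | decay of inhibition |
| `familiarity` | *λᵢ = λ_min + ½(nᵢ+1)⁻ᵖ* | observation-count learning rates |
| `compact` | *wᵢ ← wᵢ + λᵢ aᵢ fᵢ (y − ŷ) − I[wᵢ<0] ρ wᵢ* | competitive attention *a = g/‖g‖ₘ*, *g = η∘f*, with salience *η* following gradient descent on squared error |

Crucially the inter-trial intervals (context-only steps) and retention
intervals (featureless steps) are simulated too — that is where context
weights, and only negative weights under decay, change.

Fifteen experiment builders (`fearsim.build`) reproduce the standard
paradigm battery: ABA/ABC/AAB renewal, occasion-setting renewal,
spontaneous recovery and its predicted context dependence,
reinstatement and its context specificity, non-extinction of a
conditioned inhibitor, forgetting of inhibition, CS pre-exposure
(latent inhibition), deepened (compound) extinction, unpaired shocks
during extinction, multi-context extinction, and gradual extinction.
Every paradigm carries its expected **ordinal contrasts** (e.g. "test
response, Different > Same"), which the battery evaluates pass/fail —
the models make directional claims, not quantitative fits.

## Worked example

```bash
python examples/extinction_decomposition.py
```

```
with a context feature:
  final extinction-trial prediction  y_hat = 0.0000
  CS weight  w_CS  = +0.4792   (threat association survives)
  context    w_A   = -0.4792   (context became a safety signal)
context-blind learner:
  CS weight  w_CS  = +0.000022  (pure unlearning: association erased)
```

After 10 conditioning and 30 extinction trials (basic model, λ = 0.3)
the fear response is gone either way, but the context-aware learner
still carries half the threat association, exactly cancelled by context
inhibition. Remove the context (renewal), let its inhibition decay
(spontaneous recovery), or recharge it with shocks (reinstatement) and
fear returns. The other scripts in `examples/` walk through each
phenomenon; each prints the contrast values it computes.

The same battery is available from the shell:

```bash
fearsim list                      # paradigms, variants, default parameters
fearsim run --paradigm renewal_aba --out out/   # trajectories + report + manifest
fearsim battery                   # all paradigms; exit 0 iff every contrast passes
```

`fearsim battery` ends with `19/19 contrasts passed`. Custom
experiments can be written as JSON/YAML design files (see
`examples/custom_design.py` and `src/fearsim/design.schema.json`) and
run with `fearsim run --design my_design.json`.

## Layout

- `src/fearsim/schedule.py` — declarative designs, validation, expansion to time steps
- `src/fearsim/features.py` — elemental/configural feature bases
- `src/fearsim/models.py` — the five learner variants and the trajectory runner
- `src/fearsim/paradigms.py` — the experiment builders and their contrasts
- `src/fearsim/metrics.py` — response summaries and contrast evaluation
- `src/fearsim/cli.py` — the `fearsim` command
- `docs/methods.md` — modelling assumptions, parameter meanings, design choices, limitations
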