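# Methods

## Model family

All five learners are trial-level (strictly, *step*-level) error-driven
associative models. On every time step the learner observes a binary
cue vector over the stimulus catalog, featurizes it, emits a predicted
US value ŷ, observes the binary US, and updates its state. ŷ is taken
as the (unitless) fear response: freezing or suppression is assumed to
be an increasing function of ŷ, so all claims the simulator evaluates
are ordinal comparisons of ŷ between groups or trial blocks, never
fitted response magnitudes. There is no stochastic element anywhere: a
group is one deterministic run representing average behaviour, and
between-group designs compare deterministic runs. Consequently the
contrast margins (below) guard against floating-point noise, not
sampling error.

### Prediction

ŷ = max(Σᵢ fᵢ wᵢ, 0). Positive rectification is not cosmetic: with a
linear sum, a conditioned inhibitor presented alone would produce ŷ < 0,
hence a positive prediction error, and would be unlearned by mere
exposure — contrary to the classic finding that exposed and unexposed
inhibitors retain equal power. `rectify=False` is retained solely to
demonstrate that failure mode. The `compact` variant rescales features
by attention before summing: ŷ = max(Σᵢ aᵢ fᵢ wᵢ, 0).

### Features

Elemental features are one per stimulus; each context is a single
elemental feature standing for all of a chamber's background cues.
Configural features (used by `configural` and `compact`) are generated
for every CS×CS and CS×context pair and behave as interaction terms:
active only when both constituents are present. Context×context pairs
are omitted because contexts never co-occur in a schedule, so those
features could never activate; any generated-but-unused feature keeps
w = 0 and is inert, which is why generating a superset is safe. The
configural basis exists from the first step of a run; representations
in which configurations appear only at extinction are out of scope.
`build_basis(..., include_contexts=False)` implements the deliberately
impoverished context-blind learner used to show that without a context
representation, extinction is pure unlearning.

### Update rules and step order

Within a step the order is fixed and matters: featurize → attention
(compact) → predict → increment observation counts and compute λᵢ
(familiarity/compact) → salience update (compact) → weight update. The
salience and weight updates both read the prediction and attention
weights computed at the top of the step; counts are incremented
*before* the learning rate is computed, so the first observation of a
feature already uses λᵢ = λ_min + ½·2⁻ᵖ rather than λ_min + ½.

Decay of inhibition (−I[wᵢ<0] ρ wᵢ) applies on **every** time step —
trials, ITIs and delays — and to every negative weight whether or not
its feature is present, because the decay term is not gated by fᵢ. A
retention interval is therefore nothing but a long run of featureless
steps, during which a negative weight contracts exactly by (1−ρ)ᵗ and
positive weights do not move. The indicator is strict (wᵢ < 0, no
epsilon); a weight exactly at zero neither decays nor is pushed below.

On steps with no active features (delays) the compact variant skips
attention entirely — the m-norm of g is zero and attention is
undefined — predicting ŷ = 0 and performing no count, salience or
learning-term updates; weight decay still applies. Salience is clipped
below at η_floor = 1e−4 after its gradient step (a negative salience
would break the m-norm); the clip is logged when it fires. The
salience update is exactly gradient descent on squared prediction
error at interior points, which the tests verify against a central
finite difference to 1e−6.

### Initial state

w = 0 (novel cues carry no associations), n = 0, η = 1 (all features
start equally salient).

## Parameters

| symbol | meaning | default(s) |
|---|---|---|
| λ | fixed learning-rate parameter | 0.3 (basic/decay), 0.2 (configural) |
| ρ | per-step decay rate of negative weights | 0.002 (decay), 0.01 (compact) |
| λ_min | asymptotic minimum learning rate | 0.1 (familiarity), 0.15 (compact) |
| p | familiarity exponent | 1.5 (familiarity), 0.5 (compact) |
| μ | salience step size | 1.5 |
| m | attention-norm order (lower = fiercer competition) | 8.0 |

These are the hand-set values used by the paradigm battery (each
paradigm's defaults are visible via `fearsim list`). They were chosen
to produce the ordinal patterns robustly, not fitted to data; the
contrasts are insensitive to moderate changes (e.g. doubling extinction
trial counts, which the tests exercise).

## Schedules

Every trial occupies one time step and is preceded by `iti_steps`
(default 5) context-only steps; the learner updates during ITIs, which
is what keeps context weights moderate during conditioning (they are
partially unlearned between trials) and what lets unsignalled-shock
excitation of a context wash out before test. No steps follow the
final trial of a stage. Delay stages present no stimuli at all: a
retention interval is spent in the home cage, not in any experimental
context, so decay is not confounded with context learning. Trial order
within a stage is exactly the order written in the stage (a round-robin
helper interleaves trial types for intermixed schedules such as A+ /
A.X− inhibition training). Time is unitless; no mapping from steps to
minutes or days is attempted, so "1000 steps" is an arbitrary long
interval, not 35 days.

Default trial counts where the underlying experiments do not pin them
down: 10 conditioning, 30 extinction, 4 test trials, 1000-step delays;
conditioned-inhibition training uses 20 round-robin blocks. These are
enough for each stage to approach its zero-error fixed point at the
default learning rates. Gradual extinction uses 24 extinction trials
with reinforced trials at positions {1, 4, 9, 16} (gradual) and the
mirror image {9, 16, 21, 24} (gradual-reverse): decreasing
vs. increasing inter-reinforcer spacing realizes a contingency that
thins over time vs. one that grows, and the resulting contrasts are
directionally robust to the exact placement. Reinstatement uses 4
unsignalled shocks. Multi-context extinction splits the same total
number of extinction trials (10+10+10 vs 30) so that exposure is
equated and only the context switches differ.

## Measurement and contrasts

A response summary is the mean ŷ over a stage's *trial* steps (ITIs
and delays excluded), optionally filtered by trial type or restricted
to the last k trials; "degree of renewal" is the test mean minus the
final extinction trial. A contrast is an ordinal claim between two
summaries (or two differences of summaries, for the
spontaneous-recovery-by-context interaction), evaluated with a margin:
`greater`/`less` require a difference of at least 0.01, `approx_equal`
a difference of at most 0.02. Because test trials are unreinforced,
testing extinguishes: test responses decline within the test stage, and
where a design tests two trial types their errors would bleed into each
other. The forgetting-of-inhibition paradigm therefore tests A and A.X
in separate groups (a between-subjects test), matching how retention
experiments avoid the same contamination.

## What the battery does and does not show

The battery demonstrates that these model variants, under one shared
schedule convention, jointly reproduce the directional structure of the
extinction/return-of-fear literature, including the cross-cutting
prediction that everything reducing context inhibition (compound cues,
unpaired shocks, context switches, early partial reinforcement)
deepens extinction. It does not show quantitative adequacy: responses
are unitless, groups are noiseless averages, stimulus intensities are
binary, and no parameter was estimated from data. Several known
empirical results are deliberately outside the models' reach and out of
scope here: within-subjects spontaneous recovery (requires CS-specific
inhibition), the three-stimulus compound-extinction reversal,
occasion-setting designs in which the *conditioning* context modulates
a CS extinguished elsewhere, context specificity of the pre-exposure
effect, and split excitatory/inhibitory weight decompositions. The
configural variant also inherits the known over-prediction that
conditioned responding is context dependent (faster extinction after a
context switch).

## Numerical notes

All state is float64; runs raise immediately on non-finite state. The
vectorized step is verified against an independent scalar-loop
transcription of each variant's pseudocode to 1e−12 on random short
schedules. Ties and boundaries: I[w<0] is strict; ŷ at exactly zero
produces zero error on US-absent steps; the familiarity count for an
absent feature does not advance, so its λᵢ is unchanged. Designs are
validated (label uniqueness, cross-references, trials-xor-delay,
non-negative step counts) before expansion; validation returns a list
of human-readable violations and never throws, while `expand` refuses
invalid designs.
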