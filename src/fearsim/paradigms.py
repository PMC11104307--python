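"""Builders for the simulated conditioning experiments.

Each builder returns a :class:`Paradigm`: the full between-groups design,
the model variant and parameters used to simulate it, and the ordinal
contrasts the experiment is known (or predicted) to show.  Running every
paradigm with its defaults and checking every contrast is the package's
regression battery.

Conventions shared by all builders (all overridable per builder):

* trial counts — conditioning 10, extinction 30, test 4;
* ITI — 5 context-only steps before every trial;
* retention intervals ("delay") — 1000 featureless steps (home cage, not
  any experimental context);
* intermixed training (e.g. A+ / A.X- conditioned-inhibition schedules)
  interleaves trial types round-robin;
* stage labels — "conditioning", "extinction", "delay", "test" (plus
  suffixes where a paradigm needs several of a kind).

Test stages use unreinforced trials, so learning continues during test;
test trial counts are kept small for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

from .metrics import (
    APPROX_EQUAL,
    GREATER,
    Cell,
    CellDifference,
    ContrastSpec,
    ContrastResult,
    evaluate,
)
from .models import ModelParams, Trajectory, run
from .schedule import (
    DEFAULT_ITI,
    Design,
    Stage,
    StimulusCatalog,
    TrialSpec,
    round_robin,
    validate_design,
)

__all__ = [
    "Paradigm",
    "PARADIGM_NAMES",
    "build",
    "available",
    "simulate",
    "run_and_evaluate",
]


@dataclass(frozen=True)
class Paradigm:
    """A named experiment: design + model + expected ordinal outcomes."""

    name: str
    description: str
    params: ModelParams
    design: Design
    contrasts: tuple[ContrastSpec, ...]

    @property
    def variant(self) -> str:
        return self.params.variant

    def with_variant(self, variant: str, **overrides) -> "Paradigm":
        """Same design and contrasts, run under a different model variant."""
        return replace(self, params=ModelParams.defaults(variant, **overrides))


def simulate(paradigm: Paradigm) -> dict[str, Trajectory]:
    """Run every group of a paradigm; returns group -> trajectory."""
    return {
        g: run(paradigm.design, g, paradigm.params)
        for g in paradigm.design.group_labels
    }


def run_and_evaluate(
    paradigm: Paradigm,
) -> tuple[dict[str, Trajectory], list[ContrastResult]]:
    trajs = simulate(paradigm)
    return trajs, evaluate(paradigm.contrasts, trajs)


# ---------------------------------------------------------------------------
# shared shorthand


def _cs_trials() -> dict[str, TrialSpec]:
    return {
        "CS+": TrialSpec("CS+", {"CS"}, 1),
        "CS-": TrialSpec("CS-", {"CS"}, 0),
        "US": TrialSpec("US", (), 1),  # unsignalled shock
        "ctx": TrialSpec("ctx", (), 0),  # plain context exposure
    }


def _stage(label, context, trials, iti=DEFAULT_ITI) -> Stage:
    return Stage(label=label, context=context, trials=tuple(trials), iti_steps=iti)


def _delay(steps, label="delay") -> Stage:
    return Stage(label=label, context=None, trials=(), delay_steps=steps)


def _test_cell(group, trial_name=None) -> Cell:
    return Cell(group=group, stage="test", trial_name=trial_name)


# ---------------------------------------------------------------------------
# renewal family


def renewal_aba(n_cond=10, n_ext=30, n_test=4, iti=DEFAULT_ITI) -> Paradigm:
    """ABA renewal: condition in A, extinguish in B, test back in A.

    The extinction context becomes a safety signal (conditioned
    inhibitor); removing it at test uncovers the surviving CS-US
    association, so the Different group out-responds the Same group.
    """
    cat = StimulusCatalog(("CS",), ("A", "B"))
    cond = _stage("conditioning", "A", ["CS+"] * n_cond, iti)
    test = _stage("test", "A", ["CS-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "Same": (cond, _stage("extinction", "A", ["CS-"] * n_ext, iti), test),
            "Different": (cond, _stage("extinction", "B", ["CS-"] * n_ext, iti), test),
        },
    )
    contrasts = (
        ContrastSpec(
            "ABA renewal: Different > Same at test",
            _test_cell("Different"),
            _test_cell("Same"),
            GREATER,
        ),
        ContrastSpec(
            "ABA: test exceeds end of extinction (Different)",
            _test_cell("Different"),
            Cell("Different", "extinction", tail=1),
            GREATER,
        ),
    )
    return Paradigm(
        "renewal_aba",
        "ABA renewal (context change after extinction restores fear)",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


def renewal_abc(n_cond=10, n_ext=30, n_test=4, iti=DEFAULT_ITI) -> Paradigm:
    """ABC renewal: conditioning, extinction and test each in a new context."""
    cat = StimulusCatalog(("CS",), ("A", "B", "C"))
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "ABC": (
                _stage("conditioning", "A", ["CS+"] * n_cond, iti),
                _stage("extinction", "B", ["CS-"] * n_ext, iti),
                _stage("test", "C", ["CS-"] * n_test, iti),
            )
        },
    )
    contrasts = (
        ContrastSpec(
            "ABC renewal: test exceeds end of extinction",
            _test_cell("ABC"),
            Cell("ABC", "extinction", tail=1),
            GREATER,
        ),
    )
    return Paradigm(
        "renewal_abc",
        "ABC renewal (test in a third, novel context)",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


def renewal_aab(n_cond=10, n_ext=30, n_test=4, iti=DEFAULT_ITI) -> Paradigm:
    """AAB renewal: extinction in the conditioning context, test elsewhere.

    Renewal still occurs but is weaker than ABA/ABC: the shared
    conditioning/extinction context lets extinction drive the CS weight
    down further before context inhibition stalls learning.
    """
    cat = StimulusCatalog(("CS",), ("A", "B"))
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "AAB": (
                _stage("conditioning", "A", ["CS+"] * n_cond, iti),
                _stage("extinction", "A", ["CS-"] * n_ext, iti),
                _stage("test", "B", ["CS-"] * n_test, iti),
            )
        },
    )
    contrasts = (
        ContrastSpec(
            "AAB renewal: test exceeds end of extinction",
            _test_cell("AAB"),
            Cell("AAB", "extinction", tail=1),
            GREATER,
        ),
    )
    return Paradigm(
        "renewal_aab",
        "AAB renewal (weaker than ABA/ABC)",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


def occasion_setting_renewal(n_cond=10, n_ext=30, n_test=4, iti=DEFAULT_ITI) -> Paradigm:
    """Context-specific extinction of two CSs; test matched vs mismatched.

    Two CSs are conditioned together, then extinguished in two different
    contexts.  Testing each CS in the *other* CS's extinction context
    (mismatch) restores fear even though both test contexts underwent
    extinction — an occasion-setting effect carried by CS x context
    configural features, which the elemental-only model cannot show.
    """
    cat = StimulusCatalog(("CS1", "CS2"), ("A", "B", "C"))
    trials = {
        "CS1+": TrialSpec("CS1+", {"CS1"}, 1),
        "CS2+": TrialSpec("CS2+", {"CS2"}, 1),
        "CS1-": TrialSpec("CS1-", {"CS1"}, 0),
        "CS2-": TrialSpec("CS2-", {"CS2"}, 0),
    }
    cond = _stage(
        "conditioning", "A", round_robin({"CS1+": n_cond, "CS2+": n_cond}), iti
    )
    ext_b = _stage("extinction_B", "B", ["CS1-"] * n_ext, iti)
    ext_c = _stage("extinction_C", "C", ["CS2-"] * n_ext, iti)
    design = Design(
        catalog=cat,
        trial_specs=trials,
        groups={
            "Matched": (
                cond,
                ext_b,
                ext_c,
                _stage("test_B", "B", ["CS1-"] * n_test, iti),
                _stage("test_C", "C", ["CS2-"] * n_test, iti),
            ),
            "Mismatched": (
                cond,
                ext_b,
                ext_c,
                _stage("test_B", "B", ["CS2-"] * n_test, iti),
                _stage("test_C", "C", ["CS1-"] * n_test, iti),
            ),
        },
    )
    contrasts = (
        ContrastSpec(
            "occasion setting: mismatched CS > matched CS (context B)",
            Cell("Mismatched", "test_B"),
            Cell("Matched", "test_B"),
            GREATER,
        ),
        ContrastSpec(
            "occasion setting: mismatched CS > matched CS (context C)",
            Cell("Mismatched", "test_C"),
            Cell("Matched", "test_C"),
            GREATER,
        ),
    )
    return Paradigm(
        "occasion_setting_renewal",
        "renewal from CS/extinction-context mismatch (configural features)",
        ModelParams.defaults("configural"),
        design,
        contrasts,
    )


# ---------------------------------------------------------------------------
# spontaneous recovery and reinstatement


def spontaneous_recovery(
    delays=(0, 1000), n_cond=10, n_ext=30, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Fear recovers with time since extinction (decay of inhibition).

    One group per retention interval; inhibitory context weight decays
    during the featureless delay while the excitatory CS weight does
    not, so the test response grows with the delay.
    """
    cat = StimulusCatalog(("CS",), ("A",))
    groups = {}
    for d in delays:
        stages = [
            _stage("conditioning", "A", ["CS+"] * n_cond, iti),
            _stage("extinction", "A", ["CS-"] * n_ext, iti),
        ]
        if d > 0:
            stages.append(_delay(d))
        stages.append(_stage("test", "A", ["CS-"] * n_test, iti))
        groups[f"delay{d}"] = tuple(stages)
    design = Design(catalog=cat, trial_specs=_cs_trials(), groups=groups)
    ordered = sorted(delays)
    contrasts = tuple(
        ContrastSpec(
            f"spontaneous recovery: delay{b} > delay{a} at test",
            _test_cell(f"delay{b}"),
            _test_cell(f"delay{a}"),
            GREATER,
        )
        for a, b in zip(ordered, ordered[1:])
    )
    return Paradigm(
        "spontaneous_recovery",
        "return of fear with the passage of time after extinction",
        ModelParams.defaults("decay"),
        design,
        contrasts,
    )


def sr_context_dependence(
    delay=1000, n_cond=10, n_ext=30, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Predicted interaction: recovery needs the extinction context.

    2x2 design (test context Same/Different x Immediate/Delay).  If
    spontaneous recovery is decay of *context* inhibition, the delay
    should matter only when the test happens where that inhibition used
    to act: (Same/Delay - Same/Immediate) > (Different/Delay -
    Different/Immediate).
    """
    cat = StimulusCatalog(("CS",), ("A", "B"))
    groups = {}
    for ctx_name, test_ctx in (("same", "A"), ("diff", "B")):
        for d_name, d in (("immediate", 0), ("delay", delay)):
            stages = [
                _stage("conditioning", "A", ["CS+"] * n_cond, iti),
                _stage("extinction", "A", ["CS-"] * n_ext, iti),
            ]
            if d > 0:
                stages.append(_delay(d))
            stages.append(_stage("test", test_ctx, ["CS-"] * n_test, iti))
            groups[f"{ctx_name}_{d_name}"] = tuple(stages)
    design = Design(catalog=cat, trial_specs=_cs_trials(), groups=groups)
    contrasts = (
        ContrastSpec(
            "recovery (delay - immediate) larger in extinction context",
            CellDifference(_test_cell("same_delay"), _test_cell("same_immediate")),
            CellDifference(_test_cell("diff_delay"), _test_cell("diff_immediate")),
            GREATER,
        ),
    )
    return Paradigm(
        "sr_context_dependence",
        "novel prediction: spontaneous recovery is context dependent",
        ModelParams.defaults("decay"),
        design,
        contrasts,
    )


def reinstatement(n_cond=10, n_ext=30, n_shocks=4, n_test=4, iti=DEFAULT_ITI) -> Paradigm:
    """Unsignalled shocks after extinction restore responding to the CS.

    The shocks push the (inhibitory) context weight back up, removing
    the safety signal that was masking the surviving CS association.
    """
    cat = StimulusCatalog(("CS",), ("A",))
    cond = _stage("conditioning", "A", ["CS+"] * n_cond, iti)
    ext = _stage("extinction", "A", ["CS-"] * n_ext, iti)
    test = _stage("test", "A", ["CS-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "ExtraShock": (cond, ext, _stage("shocks", "A", ["US"] * n_shocks, iti), test),
            "Control": (cond, ext, _stage("shocks", "A", ["ctx"] * n_shocks, iti), test),
        },
    )
    contrasts = (
        ContrastSpec(
            "reinstatement: ExtraShock > Control at test",
            _test_cell("ExtraShock"),
            _test_cell("Control"),
            GREATER,
        ),
    )
    return Paradigm(
        "reinstatement",
        "return of fear after post-extinction unsignalled shocks",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


def reinstatement_context(
    n_cond=10, n_ext=30, n_shocks=4, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Reinstatement is context specific: shocks act only where delivered."""
    cat = StimulusCatalog(("CS",), ("A", "B"))
    cond = _stage("conditioning", "A", ["CS+"] * n_cond, iti)
    ext = _stage("extinction", "A", ["CS-"] * n_ext, iti)
    test = _stage("test", "A", ["CS-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "SameContext": (cond, ext, _stage("shocks", "A", ["US"] * n_shocks, iti), test),
            "OtherContext": (cond, ext, _stage("shocks", "B", ["US"] * n_shocks, iti), test),
        },
    )
    contrasts = (
        ContrastSpec(
            "reinstatement context specificity: shocks in test context > elsewhere",
            _test_cell("SameContext"),
            _test_cell("OtherContext"),
            GREATER,
        ),
    )
    return Paradigm(
        "reinstatement_context",
        "shocks reinstate fear only in the context where they occur",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


# ---------------------------------------------------------------------------
# conditioned inhibition and pre-exposure


def inhibitor_nonextinction(
    n_blocks=20, n_exposure=30, n_test=2, iti=DEFAULT_ITI, rectify=True
) -> Paradigm:
    """Exposing a conditioned inhibitor alone does not extinguish it.

    A+ / A.X- / A.Y- training makes X and Y safety signals.  X is then
    presented alone many times; with rectified prediction the predicted
    US is already zero on those trials, so there is no error and X's
    negative weight survives, leaving A.X and A.Y equally suppressed at
    test.  With linear (unrectified) prediction the same schedule would
    wrongly drive X's weight back to zero.
    """
    cat = StimulusCatalog(("A", "X", "Y"), ("CTX",))
    trials = {
        "A+": TrialSpec("A+", {"A"}, 1),
        "A.X-": TrialSpec("A.X-", {"A", "X"}, 0),
        "A.Y-": TrialSpec("A.Y-", {"A", "Y"}, 0),
        "X-": TrialSpec("X-", {"X"}, 0),
    }
    design = Design(
        catalog=cat,
        trial_specs=trials,
        groups={
            "main": (
                _stage(
                    "training",
                    "CTX",
                    round_robin({"A+": n_blocks, "A.X-": n_blocks, "A.Y-": n_blocks}),
                    iti,
                ),
                _stage("exposure", "CTX", ["X-"] * n_exposure, iti),
                _stage(
                    "test",
                    "CTX",
                    round_robin({"A.X-": n_test, "A.Y-": n_test}),
                    iti,
                ),
            )
        },
    )
    contrasts = (
        ContrastSpec(
            "inhibitor non-extinction: exposed (A.X) ~ unexposed (A.Y) at test",
            _test_cell("main", "A.X-"),
            _test_cell("main", "A.Y-"),
            APPROX_EQUAL,
        ),
    )
    return Paradigm(
        "inhibitor_nonextinction",
        "a safety signal survives repeated presentation on its own",
        ModelParams.defaults("basic", rectify=rectify),
        design,
        contrasts,
    )


def forgetting_of_inhibition(
    delay=1000, n_blocks=20, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Inhibition fades with time while excitation is retained.

    A+, B+, B.X- training; after a long retention interval the response
    to A alone is unchanged but the compound A.X loses the protection X
    used to provide, because X's negative weight has decayed.  The test
    is between subjects (one group per delay x test-trial-type cell):
    unreinforced test trials extinguish whatever they present, so
    interleaving A and A.X tests within one group would let each trial
    type contaminate the other's measurement.
    """
    cat = StimulusCatalog(("A", "B", "X"), ("CTX",))
    trials = {
        "A+": TrialSpec("A+", {"A"}, 1),
        "B+": TrialSpec("B+", {"B"}, 1),
        "B.X-": TrialSpec("B.X-", {"B", "X"}, 0),
        "A-": TrialSpec("A-", {"A"}, 0),
        "A.X-": TrialSpec("A.X-", {"A", "X"}, 0),
    }
    train = _stage(
        "training",
        "CTX",
        round_robin({"A+": n_blocks, "B+": n_blocks, "B.X-": n_blocks}),
        iti,
    )
    groups = {}
    for d_name, stages in (("NoDelay", (train,)), ("Delay", (train, _delay(delay)))):
        for t_name, trial in (("A", "A-"), ("AX", "A.X-")):
            groups[f"{d_name}_{t_name}"] = stages + (
                _stage("test", "CTX", [trial] * n_test, iti),
            )
    design = Design(catalog=cat, trial_specs=trials, groups=groups)
    contrasts = (
        ContrastSpec(
            "forgetting of inhibition: A.X responds more after delay",
            _test_cell("Delay_AX"),
            _test_cell("NoDelay_AX"),
            GREATER,
        ),
        ContrastSpec(
            "excitation retained: A alone ~ equal across delay",
            _test_cell("Delay_A"),
            _test_cell("NoDelay_A"),
            APPROX_EQUAL,
        ),
    )
    return Paradigm(
        "forgetting_of_inhibition",
        "a discrete conditioned inhibitor loses power over a retention interval",
        ModelParams.defaults("decay"),
        design,
        contrasts,
    )


def preexposure(n_pre=30, n_cond=10, iti=DEFAULT_ITI) -> Paradigm:
    """CS pre-exposure slows subsequent conditioning (latent inhibition).

    Unreinforced pre-exposure makes the CS familiar, lowering its
    learning rate under the familiarity principle; the control group
    receives matched plain-context trials so context familiarity is
    equated.  The fixed-rate basic model predicts no effect.
    """
    cat = StimulusCatalog(("CS",), ("A",))
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "PreExposed": (
                _stage("preexposure", "A", ["CS-"] * n_pre, iti),
                _stage("acquisition", "A", ["CS+"] * n_cond, iti),
            ),
            "Control": (
                _stage("preexposure", "A", ["ctx"] * n_pre, iti),
                _stage("acquisition", "A", ["CS+"] * n_cond, iti),
            ),
        },
    )
    contrasts = (
        ContrastSpec(
            "pre-exposure effect: control acquires faster",
            Cell("Control", "acquisition"),
            Cell("PreExposed", "acquisition"),
            GREATER,
        ),
    )
    return Paradigm(
        "preexposure",
        "latent inhibition: familiar cues condition more slowly",
        ModelParams.defaults("familiarity"),
        design,
        contrasts,
    )


# ---------------------------------------------------------------------------
# reducing the return of fear


def compound_extinction(
    n_cond=10, n_ext=15, n_deepen=10, delay=1000, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Deepened extinction: compound trials after separate extinction.

    Presenting the two separately-extinguished cues together summates
    their residual threat associations past the context's inhibition,
    recreating prediction error and driving extra unlearning; after a
    retention interval the compound-trained group recovers less.
    """
    cat = StimulusCatalog(("A", "X"), ("CTX",))
    trials = {
        "A+": TrialSpec("A+", {"A"}, 1),
        "X+": TrialSpec("X+", {"X"}, 1),
        "A-": TrialSpec("A-", {"A"}, 0),
        "X-": TrialSpec("X-", {"X"}, 0),
        "A.X-": TrialSpec("A.X-", {"A", "X"}, 0),
    }
    cond = _stage("conditioning", "CTX", round_robin({"A+": n_cond, "X+": n_cond}), iti)
    ext = _stage("extinction", "CTX", round_robin({"A-": n_ext, "X-": n_ext}), iti)
    test = _stage("test", "CTX", ["X-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=trials,
        groups={
            "Compound": (
                cond,
                ext,
                _stage("deepening", "CTX", ["A.X-"] * n_deepen, iti),
                _delay(delay),
                test,
            ),
            "Control": (
                cond,
                ext,
                _stage("deepening", "CTX", ["X-"] * n_deepen, iti),
                _delay(delay),
                test,
            ),
        },
    )
    contrasts = (
        ContrastSpec(
            "deepened extinction: compound group recovers less",
            _test_cell("Control"),
            _test_cell("Compound"),
            GREATER,
        ),
    )
    return Paradigm(
        "compound_extinction",
        "compound presentation of extinguished cues deepens extinction",
        ModelParams.defaults("decay"),
        design,
        contrasts,
    )


def unpaired_shocks_extinction(
    n_cond=10, n_ext=30, n_shocks=10, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Unsignalled shocks during extinction reduce ABA renewal.

    Shocks keep the extinction context excitatory, preventing it from
    becoming a safety signal; the CS association must then do all the
    extinction work itself, leaving less to renew at test.
    """
    cat = StimulusCatalog(("CS",), ("A", "B"))
    cond = _stage("conditioning", "A", ["CS+"] * n_cond, iti)
    test = _stage("test", "A", ["CS-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "Unpaired": (
                cond,
                _stage(
                    "extinction",
                    "B",
                    round_robin({"CS-": n_ext, "US": n_shocks}),
                    iti,
                ),
                test,
            ),
            "Control": (cond, _stage("extinction", "B", ["CS-"] * n_ext, iti), test),
        },
    )
    contrasts = (
        ContrastSpec(
            "unpaired shocks reduce renewal: Control > Unpaired at test",
            _test_cell("Control"),
            _test_cell("Unpaired"),
            GREATER,
        ),
    )
    return Paradigm(
        "unpaired_shocks_extinction",
        "US-alone trials in the extinction context reduce ABA renewal",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


def multi_context_extinction(
    n_cond=10, n_ext_total=30, n_test=4, iti=DEFAULT_ITI
) -> Paradigm:
    """Extinction spread over several contexts reduces renewal.

    Each context switch removes the previous context's inhibition, so
    prediction error reappears and the CS association keeps unlearning;
    a single-context group stalls once its one context is inhibitory.
    Tested in a novel context so neither group has a safety signal.
    """
    cat = StimulusCatalog(("CS",), ("A", "B", "C", "D", "E"))
    per_ctx = n_ext_total // 3
    cond = _stage("conditioning", "A", ["CS+"] * n_cond, iti)
    test = _stage("test", "E", ["CS-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "Multi": (
                cond,
                _stage("extinction_1", "B", ["CS-"] * per_ctx, iti),
                _stage("extinction_2", "C", ["CS-"] * per_ctx, iti),
                _stage("extinction_3", "D", ["CS-"] * per_ctx, iti),
                test,
            ),
            "Single": (
                cond,
                _stage("extinction_1", "B", ["CS-"] * n_ext_total, iti),
                test,
            ),
        },
    )
    contrasts = (
        ContrastSpec(
            "multi-context extinction: Single > Multi in novel test context",
            _test_cell("Single"),
            _test_cell("Multi"),
            GREATER,
        ),
    )
    return Paradigm(
        "multi_context_extinction",
        "splitting extinction across contexts produces more unlearning",
        ModelParams.defaults("basic"),
        design,
        contrasts,
    )


#: 1-indexed reinforced trial positions within the extinction stage
GRADUAL_REINFORCED = (1, 4, 9, 16)
GRADUAL_REVERSE_REINFORCED = (9, 16, 21, 24)


def gradual_extinction(
    n_cond=10,
    n_ext=24,
    delay=1000,
    n_test=4,
    iti=DEFAULT_ITI,
    reinforced=GRADUAL_REINFORCED,
    reinforced_reverse=GRADUAL_REVERSE_REINFORCED,
) -> Paradigm:
    """Gradually thinning the CS-US contingency protects extinction.

    Occasional reinforced trials early in extinction keep the CS a
    usable predictor, so competitive attention stays on the CS rather
    than shifting to the context; the CS association is driven down
    further and less fear returns after a retention interval.  The
    mirror-image schedule (reinforcers late) and standard extinction
    lack this protection.
    """
    cat = StimulusCatalog(("CS",), ("A",))

    def ext_stage(positions) -> Stage:
        seq = tuple(
            "CS+" if (i + 1) in positions else "CS-" for i in range(n_ext)
        )
        return _stage("extinction", "A", seq, iti)

    cond = _stage("conditioning", "A", ["CS+"] * n_cond, iti)
    test = _stage("test", "A", ["CS-"] * n_test, iti)
    design = Design(
        catalog=cat,
        trial_specs=_cs_trials(),
        groups={
            "Gradual": (cond, ext_stage(set(reinforced)), _delay(delay), test),
            "GradualReverse": (
                cond,
                ext_stage(set(reinforced_reverse)),
                _delay(delay),
                test,
            ),
            "Standard": (cond, ext_stage(set()), _delay(delay), test),
        },
    )
    contrasts = (
        ContrastSpec(
            "gradual extinction: less recovery than standard",
            _test_cell("Standard"),
            _test_cell("Gradual"),
            GREATER,
        ),
        ContrastSpec(
            "gradual extinction: less recovery than gradual-reverse",
            _test_cell("GradualReverse"),
            _test_cell("Gradual"),
            GREATER,
        ),
    )
    return Paradigm(
        "gradual_extinction",
        "slowly decreasing CS-US contingency reduces spontaneous recovery",
        ModelParams.defaults("compact"),
        design,
        contrasts,
    )


# ---------------------------------------------------------------------------
# registry

_BUILDERS: dict[str, Callable[..., Paradigm]] = {
    "renewal_aba": renewal_aba,
    "renewal_abc": renewal_abc,
    "renewal_aab": renewal_aab,
    "occasion_setting_renewal": occasion_setting_renewal,
    "spontaneous_recovery": spontaneous_recovery,
    "sr_context_dependence": sr_context_dependence,
    "reinstatement": reinstatement,
    "reinstatement_context": reinstatement_context,
    "inhibitor_nonextinction": inhibitor_nonextinction,
    "forgetting_of_inhibition": forgetting_of_inhibition,
    "preexposure": preexposure,
    "compound_extinction": compound_extinction,
    "unpaired_shocks_extinction": unpaired_shocks_extinction,
    "multi_context_extinction": multi_context_extinction,
    "gradual_extinction": gradual_extinction,
}

PARADIGM_NAMES: tuple[str, ...] = tuple(_BUILDERS)


def available() -> tuple[str, ...]:
    return PARADIGM_NAMES


def build(name: str, **kwargs) -> Paradigm:
    """Build a paradigm by name; keyword arguments reach the builder.

    Every built paradigm is guaranteed to pass design validation.
    """
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown paradigm {name!r}; available: {', '.join(PARADIGM_NAMES)}"
        )
    paradigm = _BUILDERS[name](**kwargs)
    violations = validate_design(paradigm.design)
    if violations:  # pragma: no cover - builders are supposed to be valid
        raise AssertionError(f"builder {name} produced invalid design: {violations}")
    return paradigm
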